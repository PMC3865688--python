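"""Readers and writers for the plain-text interchange formats.

Internally all coordinates are 0-based half-open.  Emitted files follow the
conventions of their formats: TSV marker/count tables and bedGraph-style
tracks use 1-based positions like VCF, BED files are 0-based half-open.
FASTA goes through Biopython.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tetrada.synthetic_data import (
    Crossover,
    DHTruth,
    GenomeModel,
    MeiosisTruth,
    TetradTruth,
    Tract,
)

# ---------------------------------------------------------------------------
# tables


def write_marker_table(path, markers: pd.DataFrame):
    out = markers.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_marker_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["pos"] = df["pos"] - 1
    df["triallelic"] = df["triallelic"].astype(bool)
    df["decoy"] = df["decoy"].astype(np.int8)
    df["recipient_class"] = df["recipient_class"].astype(np.int8)
    return df


def write_allele_counts(path, counts: pd.DataFrame):
    out = counts.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_allele_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    df["pos"] = df["pos"] - 1
    return df


def write_bed(path, df: pd.DataFrame, extra_cols=()):
    cols = ["chrom", "start", "end", *extra_cols]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path, extra_cols=()) -> pd.DataFrame:
    names = ["chrom", "start", "end", *extra_cols]
    df = pd.read_csv(path, sep="\t", names=names, dtype={"chrom": str})
    return df


def write_bedgraph(path, track: pd.DataFrame):
    track[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "value"], dtype={"chrom": str}
    )


def write_fasta(path, sequences: dict[str, str]):
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# genome model


def write_genome_model(outdir, genome: GenomeModel):
    outdir = Path(outdir)
    meta = {
        "chromosomes": [[c, int(s)] for c, s in genome.chromosomes],
        "pericentromere": {c: [int(s), int(e)] for c, (s, e) in genome.pericentromere.items()},
    }
    (outdir / "genome.json").write_text(json.dumps(meta, indent=1))
    if len(genome.genes):
        write_bed(outdir / "genes.bed", genome.genes, extra_cols=["strand"])
    if len(genome.transposons):
        write_bed(outdir / "transposons.bed", genome.transposons)
    if len(genome.duplications):
        write_bed(outdir / "duplications.bed", genome.duplications)


def read_genome_model(outdir) -> GenomeModel:
    outdir = Path(outdir)
    meta = json.loads((outdir / "genome.json").read_text())
    def _bed(name, extra=()):
        p = outdir / name
        if p.exists():
            return read_bed(p, extra_cols=extra)
        cols = ["chrom", "start", "end", *extra]
        return pd.DataFrame(columns=cols)

    return GenomeModel(
        chromosomes=[tuple(x) for x in meta["chromosomes"]],
        pericentromere={c: tuple(v) for c, v in meta["pericentromere"].items()},
        genes=_bed("genes.bed", extra=["strand"]),
        transposons=_bed("transposons.bed"),
        duplications=_bed("duplications.bed"),
    )


# ---------------------------------------------------------------------------
# truth (run-length encoded paint keeps the JSON small)


def _rle(arr: np.ndarray):
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate([[0], change])
    return [[int(i), int(arr[i])] for i in starts]


def _unrle(runs, n):
    arr = np.zeros(n, dtype=np.int8)
    for k, (start, val) in enumerate(runs):
        end = runs[k + 1][0] if k + 1 < len(runs) else n
        arr[start:end] = val
    return arr


def _meiosis_to_dict(m: MeiosisTruth):
    return {
        "name": m.name,
        "cos": [dataclasses.asdict(c) for c in m.cos],
        "tracts": [dataclasses.asdict(t) for t in m.tracts],
        "paint": {str(c): _rle(a) for c, a in m.paint.items()},
        "n_markers": len(next(iter(m.paint.values()))) if m.paint else 0,
    }


def _meiosis_from_dict(d) -> MeiosisTruth:
    n = d["n_markers"]
    return MeiosisTruth(
        name=d["name"],
        cos=[Crossover(c["chrom"], c["pos"], tuple(c["chromatids"])) for c in d["cos"]],
        tracts=[Tract(**t) for t in d["tracts"]],
        paint={int(c): _unrle(runs, n) for c, runs in d["paint"].items()},
    )


def write_truth(path, truth: TetradTruth):
    doc = {
        "meioses": [_meiosis_to_dict(m) for m in truth.meioses],
        "dh": [
            {"sample": d.sample, "gamete": d.gamete, "meiosis": _meiosis_to_dict(d.meiosis)}
            for d in truth.dh
        ],
        "cnv": truth.cnv,
    }
    Path(path).write_text(json.dumps(doc))


def read_truth(path) -> TetradTruth:
    doc = json.loads(Path(path).read_text())
    return TetradTruth(
        meioses=[_meiosis_from_dict(m) for m in doc["meioses"]],
        dh=[
            DHTruth(
                sample=d["sample"],
                gamete=d["gamete"],
                meiosis=_meiosis_from_dict(d["meiosis"]),
            )
            for d in doc["dh"]
        ],
        cnv={s: [tuple(x) for x in v] for s, v in doc.get("cnv", {}).items()},
    )


def write_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
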