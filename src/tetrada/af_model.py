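"""Allele-frequency model: beta fits and the equal-error genotyping cutoff.

At a homozygous marker the major-allele read frequency clusters near 1; at a
heterozygous marker near 0.5.  Fitting beta distributions to the two
observed frequency distributions gives, per coverage stratum, the cutoff c
solving

    P_het(AF >= c) = P_hom(AF <= c)

so that heterozygous and homozygous genotypes are miscalled at the same
rate.  A minimum-coverage threshold is chosen where the apparent conversion
frequency stops changing with further coverage requirements (the plateau of
the frequency-vs-coverage curve).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_STRATA = np.arange(10, 101, 10)


def clamp_frequencies(af: np.ndarray, depth: np.ndarray) -> np.ndarray:
    """Pull exact 0/1 frequencies inward by half a read's worth, 1/(2*depth)."""
    af = np.asarray(af, dtype=float).copy()
    depth = np.broadcast_to(np.asarray(depth, dtype=float), af.shape)
    half = 1.0 / (2.0 * np.maximum(depth, 1.0))
    af[af <= 0.0] = half[af <= 0.0]
    af[af >= 1.0] = 1.0 - half[af >= 1.0]
    return af


def fit_betas(af: np.ndarray, depth: np.ndarray, min_obs: int = 50) -> tuple[float, float]:
    """Maximum-likelihood beta shape pair for observed allele frequencies.

    Frequencies at exactly 0/1 are clamped inward by ``1/(2*depth)`` first.
    Method-of-moments estimates seed the MLE.  Raises on fewer than
    ``min_obs`` observations or a degenerate (constant) sample.
    """
    af = np.asarray(af, dtype=float)
    if len(af) < min_obs:
        raise ValueError(f"need >= {min_obs} observations, got {len(af)}")
    x = clamp_frequencies(af, depth)
    m, v = float(np.mean(x)), float(np.var(x))
    if np.ptp(x) == 0 or v <= 0:
        raise ValueError("degenerate (constant) allele-frequency sample")
    # method-of-moments start
    common = m * (1 - m) / v - 1
    a0, b0 = max(m * common, 1e-3), max((1 - m) * common, 1e-3)
    a, b, _, _ = stats.beta.fit(x, a0, b0, floc=0.0, fscale=1.0)
    return float(a), float(b)


def equal_error_cutoff(beta_hom: tuple[float, float], beta_het: tuple[float, float]) -> float:
    """Frequency c at which P_het(AF >= c) equals P_hom(AF <= c).

    ``beta_hom`` must sit above ``beta_het`` (higher mean).  Solved by
    bracketed root-finding to |delta| < 1e-10; by construction the two
    genotype-misassignment error rates are equal at the returned cutoff.
    """
    ah, bh = beta_hom
    ae, be = beta_het
    mean_hom = ah / (ah + bh)
    mean_het = ae / (ae + be)
    if mean_hom <= mean_het:
        raise ValueError("homozygous distribution must have the higher mean")

    def f(c):
        return stats.beta.sf(c, ae, be) - stats.beta.cdf(c, ah, bh)

    lo, hi = mean_het, mean_hom
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:  # widen toward (0, 1) if the means do not bracket
        lo, hi = 1e-9, 1 - 1e-9
        if f(lo) * f(hi) > 0:
            raise ValueError("no equal-error point between the two distributions")
    c = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    assert abs(f(c)) < 1e-10
    return float(c)


@dataclass
class CutoffModel:
    """Coverage-stratified beta fits and equal-error cutoffs.

    ``strata`` has one row per coverage bin: cov_lo, cov_hi, a_hom, b_hom,
    a_het, b_het, cutoff.  ``fixed(c)`` builds a coverage-independent model.
    """

    strata: pd.DataFrame
    min_cov: int = 1
    global_cutoff: float | None = None

    @classmethod
    def fixed(cls, cutoff: float, min_cov: int = 1) -> "CutoffModel":
        df = pd.DataFrame(
            [[0, np.inf, np.nan, np.nan, np.nan, np.nan, cutoff]],
            columns=["cov_lo", "cov_hi", "a_hom", "b_hom", "a_het", "b_het", "cutoff"],
        )
        return cls(strata=df, min_cov=min_cov, global_cutoff=cutoff)

    @classmethod
    def fit(
        cls,
        af_hom: np.ndarray,
        depth_hom: np.ndarray,
        af_het: np.ndarray,
        depth_het: np.ndarray,
        bin_width: int = 10,
        pool_above: int = 100,
        min_obs: int = 50,
        min_cov: int = 1,
        per_stratum: bool = True,
    ) -> "CutoffModel":
        """Fit betas per coverage stratum (bins of ``bin_width``, pooled above
        ``pool_above``) and derive the equal-error cutoff per stratum.

        With ``per_stratum=False`` one global pair is fitted and its cutoff
        used at every depth (both readings of a "global, coverage-dependent"
        rule are supported).
        """
        af_hom, af_het = np.asarray(af_hom, float), np.asarray(af_het, float)
        depth_hom, depth_het = np.asarray(depth_hom, float), np.asarray(depth_het, float)
        g_hom = fit_betas(af_hom, depth_hom, min_obs=min_obs)
        g_het = fit_betas(af_het, depth_het, min_obs=min_obs)
        g_cut = equal_error_cutoff(g_hom, g_het)
        rows = []
        if per_stratum:
            edges = list(np.arange(0, pool_above + 1, bin_width)) + [np.inf]
            for lo, hi in zip(edges[:-1], edges[1:]):
                sh = (depth_hom >= lo) & (depth_hom < hi)
                se = (depth_het >= lo) & (depth_het < hi)
                if sh.sum() < min_obs or se.sum() < min_obs:
                    continue
                try:
                    bh = fit_betas(af_hom[sh], depth_hom[sh], min_obs=min_obs)
                    be = fit_betas(af_het[se], depth_het[se], min_obs=min_obs)
                    cut = equal_error_cutoff(bh, be)
                except ValueError:
                    continue
                rows.append([lo, hi, *bh, *be, cut])
        if not rows:
            rows.append([0, np.inf, *g_hom, *g_het, g_cut])
        df = pd.DataFrame(
            rows, columns=["cov_lo", "cov_hi", "a_hom", "b_hom", "a_het", "b_het", "cutoff"]
        )
        return cls(strata=df, min_cov=min_cov, global_cutoff=g_cut)

    def cutoff_for(self, depth) -> np.ndarray:
        """Equal-error cutoff applicable at each depth (vectorized)."""
        depth = np.atleast_1d(np.asarray(depth, dtype=float))
        lo = self.strata["cov_lo"].to_numpy()
        cut = self.strata["cutoff"].to_numpy()
        idx = np.clip(np.searchsorted(lo, depth, side="right") - 1, 0, len(lo) - 1)
        return cut[idx]

    def to_json(self, path):
        doc = {
            "min_cov": int(self.min_cov),
            "global_cutoff": self.global_cutoff,
            "strata": self.strata.replace({np.inf: "inf"}).to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path) -> "CutoffModel":
        doc = json.loads(Path(path).read_text())
        df = pd.DataFrame(doc["strata"]).replace({"inf": np.inf})
        return cls(strata=df, min_cov=doc["min_cov"], global_cutoff=doc["global_cutoff"])


def coverage_plateau(
    cov_grid: np.ndarray, frequencies: np.ndarray, rel_tol: float = 0.10
) -> tuple[int, pd.DataFrame]:
    """Smallest coverage threshold beyond which the conversion frequency is
    stable.

    ``frequencies[i]`` is the apparent conversion frequency (converted
    markers / genotyped markers) when requiring coverage >= ``cov_grid[i]``.
    Returns the smallest grid value c* such that every consecutive relative
    change at or beyond c* stays below ``rel_tol``, plus the curve as a
    DataFrame.  If no plateau exists the maximum grid value is returned with
    a warning.
    """
    cov_grid = np.asarray(cov_grid)
    freq = np.asarray(frequencies, dtype=float)
    if len(cov_grid) != len(freq) or len(cov_grid) < 2:
        raise ValueError("grid and frequencies must align, length >= 2")
    order = np.argsort(cov_grid)
    cov_grid, freq = cov_grid[order], freq[order]
    denom = np.maximum(freq[:-1], 1e-300)
    rel = np.abs(np.diff(freq)) / denom
    rel[(freq[:-1] == 0) & (freq[1:] == 0)] = 0.0
    curve = pd.DataFrame({"min_cov": cov_grid, "frequency": freq})
    stable = rel < rel_tol
    # plateau start: all changes from here on are small
    ok_from = np.flatnonzero(~stable[::-1])
    if len(ok_from) == 0:
        return int(cov_grid[0]), curve
    first_bad = len(stable) - 1 - ok_from[0]
    if first_bad == len(stable) - 1:
        warnings.warn("no plateau within the coverage grid; returning its maximum")
        return int(cov_grid[-1]), curve
    return int(cov_grid[first_bad + 1]), curve
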