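"""Selective-sweep scanning with the population branch statistic family.

With one focal (resistant) and two non-focal (susceptible reference)
populations, pairwise window FST values are log-transformed into branch
lengths T = -ln(1 - FST).  The population branch statistic

    PBS = (T_f1 + T_f2 - T_12) / 2

is the focal population's branch.  Population branch excess subtracts
the genome-wide expectation of PBS given the non-focal divergence,

    PBE_w = PBS_w - T_12,w * median_w(PBS / T_12),

so that windows elevated genome-wide (drift, demography) are discounted
and only focal-specific excess differentiation stands out.  Outliers are
the top tail of the empirical PBE distribution (default top 1%, with the
5% alternative exposed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .poolseq import WindowStats

__all__ = [
    "branch_length",
    "pbs",
    "pbe",
    "pbe_scan",
    "call_outliers",
    "sweep_report",
]

_EPS = 1e-9


def branch_length(fst, eps: float = _EPS, tol: float = 1e-6):
    """Branch length T = -ln(1 - FST), clamped into [0, 1 - eps).

    Negative window-FST estimates (sampling noise of the pi-ratio
    estimator, bounded below by -1) are clamped to 0; values above 1 or
    below -1 beyond ``tol`` raise.
    """
    fst_arr = np.asarray(fst, dtype=float)
    if np.any(fst_arr < -1 - tol) or np.any(fst_arr > 1 + tol):
        raise ValueError("FST outside [-1, 1] beyond clamping tolerance")
    clamped = np.clip(fst_arr, 0.0, 1.0 - eps)
    out = -np.log1p(-clamped)
    return float(out) if np.isscalar(fst) else out


def pbs(t_f1, t_f2, t_12):
    """Focal branch length: PBS = (T_f1 + T_f2 - T_12) / 2 (may be negative)."""
    return (np.asarray(t_f1) + np.asarray(t_f2) - np.asarray(t_12)) / 2.0


def pbe(pbs_values, t_12_values, min_windows: int = 20) -> np.ndarray:
    """Per-window population branch excess.

    The genome-wide scaling is the median of PBS / T_12 over windows with
    T_12 > 0; windows with T_12 = 0 keep PBE = PBS.  Requires at least
    ``min_windows`` usable windows to estimate the median.
    """
    pbs_values = np.asarray(pbs_values, dtype=float)
    t12 = np.asarray(t_12_values, dtype=float)
    usable = t12 > 0
    if usable.sum() < min_windows:
        raise ValueError(
            f"only {int(usable.sum())} windows with T_12 > 0; need >= {min_windows}"
        )
    med = float(np.median(pbs_values[usable] / t12[usable]))
    out = pbs_values - t12 * med
    out[~usable] = pbs_values[~usable]
    return out


def pbe_scan(
    windows: WindowStats,
    focal: str,
    nonfocal: tuple[str, str],
    min_windows: int = 20,
) -> pd.DataFrame:
    """Window table of FST, branch lengths, PBS and PBE for one focal design.

    Windows with a masked FST in any of the three pairs are excluded from
    the median estimation and carry NaN PBE (they are likewise ignored by
    outlier calling).
    """
    n1, n2 = nonfocal
    if len({focal, n1, n2}) != 3:
        raise ValueError("focal and non-focal populations must be three distinct pools")
    f1 = windows.fst(focal, n1).rename(columns={"fst": "fst_f1"})
    f2 = windows.fst(focal, n2)[["chrom", "start", "fst"]].rename(columns={"fst": "fst_f2"})
    f12 = windows.fst(n1, n2)[["chrom", "start", "fst"]].rename(columns={"fst": "fst_12"})
    df = f1.merge(f2, on=["chrom", "start"]).merge(f12, on=["chrom", "start"])

    ok = df[["fst_f1", "fst_f2", "fst_12"]].notna().all(axis=1)
    for col in ("fst_f1", "fst_f2", "fst_12"):
        df["T_" + col.split("_")[1]] = np.where(ok, branch_length(df[col].fillna(0.0).to_numpy()), np.nan)
    df["pbs"] = pbs(df["T_f1"], df["T_f2"], df["T_12"])
    df["pbe"] = np.nan
    df.loc[ok, "pbe"] = pbe(df.loc[ok, "pbs"].to_numpy(), df.loc[ok, "T_12"].to_numpy(),
                            min_windows=min_windows)
    df["usable"] = ok
    return df


def call_outliers(scan: pd.DataFrame, quantile: float = 0.01) -> pd.DataFrame:
    """Flag windows at or above the empirical (1 - quantile) PBE threshold.

    Ties at the threshold are all flagged; ``rank`` is 1 for the largest
    PBE with ties broken by genomic order.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    df = scan.copy()
    usable = df["pbe"].notna()
    if not usable.any():
        raise ValueError("no usable windows to call outliers on")
    threshold = float(np.quantile(df.loc[usable, "pbe"], 1.0 - quantile))
    df["outlier"] = usable & (df["pbe"] >= threshold)
    order = df.loc[usable].sort_values(
        ["pbe", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    )
    df["rank"] = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    df.attrs["pbe_threshold"] = threshold
    df.attrs["quantile"] = quantile
    return df


def _overlaps(start: int, end: int, lo: int, hi: int) -> bool:
    return start <= hi and end >= lo


@dataclass
class GeneSweepSummary:
    """Per-gene sweep evidence for one focal population."""

    gene: str
    max_pbe: float
    outlier_overlap: bool
    pi_gene: float
    pi_flank: float
    d_gene: float
    d_flank: float
    signal: bool

    @property
    def pi_contrast(self) -> float:
        return self.pi_gene - self.pi_flank

    @property
    def d_contrast(self) -> float:
        return self.d_gene - self.d_flank


def sweep_report(
    scan: pd.DataFrame,
    diversity: pd.DataFrame,
    gene_regions: dict[str, tuple[str, int, int]],
    *,
    focal_pool: str | None = None,
    flank: int = 1_000_000,
    signal_flank: int = 25_000,
) -> dict[str, GeneSweepSummary]:
    """Summarize sweep evidence around each gene of interest.

    ``scan`` is an outlier-called PBE table; ``diversity`` the focal
    pool's window diversity table.  For each gene the report gives the
    maximum PBE within +-``flank``, whether any outlier window falls
    within the gene body +-``signal_flank`` (the per-population
    signal/no-signal call), and the gene-proximal vs flank contrast of
    pi and Tajima's D.
    """
    div = diversity
    if focal_pool is not None:
        div = div[div["pool"] == focal_pool]
    out: dict[str, GeneSweepSummary] = {}
    for gene, (chrom, gstart, gend) in gene_regions.items():
        w = scan[scan["chrom"] == chrom]
        near = w[(w["start"] <= gend + flank) & (w["end"] >= gstart - flank)]
        if near.empty:
            raise ValueError(f"gene {gene} lies outside the scanned contig bounds")
        proximal = near.apply(
            lambda r: _overlaps(r["start"], r["end"], gstart - signal_flank, gend + signal_flank),
            axis=1,
        )
        outlier_overlap = bool(near.loc[proximal, "outlier"].any()) if "outlier" in near else False
        dv = div[div["chrom"] == chrom]
        dv_near = dv[(dv["start"] <= gend + flank) & (dv["end"] >= gstart - flank)]
        dvprox = dv_near.apply(
            lambda r: _overlaps(r["start"], r["end"], gstart - signal_flank, gend + signal_flank),
            axis=1,
        )
        out[gene] = GeneSweepSummary(
            gene=gene,
            max_pbe=float(near["pbe"].max()),
            outlier_overlap=outlier_overlap,
            pi_gene=float(dv_near.loc[dvprox, "pi"].mean()),
            pi_flank=float(dv_near.loc[~dvprox, "pi"].mean()),
            d_gene=float(dv_near.loc[dvprox, "tajimas_d"].mean()),
            d_flank=float(dv_near.loc[~dvprox, "tajimas_d"].mean()),
            signal=outlier_overlap,
        )
    return out
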