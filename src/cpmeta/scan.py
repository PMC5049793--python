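"""Genome-wide scan orchestration, genomic control, loci and comparisons.

Runs the combined statistics and the conventional sample-size-weighted
Z baseline over a harmonized panel, computes genomic-control lambda,
clumps significant SNPs into loci, flags loci novel relative to the
baseline, and cross-tabulates the two methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .combine import HetNull, p_het_batch, s_het_batch, s_hom_batch
from .nullcorr import CorrMatrix
from .sumstats import ZPanel

__all__ = [
    "ScanSummary",
    "Locus",
    "CrossTab",
    "weighted_z_meta",
    "weighted_z_batch",
    "genomic_control_lambda",
    "run_scan",
    "scan_summary",
    "identify_loci",
    "novel_vs_baseline",
    "cross_tabulate",
    "forest_data",
    "qq_data",
    "manhattan_data",
]

GENOME_WIDE_P = 5e-8
SECONDARY_P = 1e-7
DEFAULT_FLANK = 500_000

_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...


@dataclass
class ScanSummary:
    method: str
    lambda_gc: float
    n_snps: int
    n_significant: int
    threshold: float = GENOME_WIDE_P


@dataclass
class Locus:
    lead_snp: str
    chromosome: str
    position: int
    lead_p: float
    window_start: int
    window_end: int
    member_snps: list[str] = field(default_factory=list)
    novel_vs_baseline: bool | None = None


def weighted_z_meta(T, n) -> tuple[float, float]:
    """Conventional fixed-effect combination z = sum(sqrt(n) T)/sqrt(sum n)."""
    T = np.asarray(T, dtype=float)
    n = np.broadcast_to(np.asarray(n, dtype=float), T.shape)
    obs = np.isfinite(T)
    if not obs.any():
        return float("nan"), float("nan")
    w = np.sqrt(n[obs])
    z = float((w * T[obs]).sum() / np.sqrt((w * w).sum()))
    return z, float(2.0 * stats.norm.sf(abs(z)))


def weighted_z_batch(Z: np.ndarray, n) -> tuple[np.ndarray, np.ndarray]:
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n = np.broadcast_to(np.asarray(n, dtype=float), Z.shape)
    obs = np.isfinite(Z)
    w = np.where(obs, np.sqrt(n), 0.0)
    num = np.nansum(w * np.where(obs, Z, 0.0), axis=1)
    den = np.sqrt((w * w).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(den > 0, num / den, np.nan)
    return z, 2.0 * stats.norm.sf(np.abs(z))


def genomic_control_lambda(values, kind: str = "p") -> float:
    """Median observed chi-square(1) statistic divided by its null median.

    ``kind`` is ``"p"`` for p-values (converted through the chi-square(1)
    inverse survival function) or ``"chi2"`` for statistics directly.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 100:
        raise ValueError("need at least 100 values for genomic control")
    if kind == "p":
        if np.any((vals <= 0) | (vals > 1)):
            raise ValueError("p-values outside (0, 1]")
        chi = stats.chi2.isf(vals, df=1)
    elif kind == "chi2":
        chi = vals
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return float(np.median(chi) / _CHI2_1_MEDIAN)


def run_scan(
    zp: ZPanel,
    R: CorrMatrix | np.ndarray,
    scheme: str = "sqrt_n",
    het_null: HetNull | None = None,
    compute_het: bool = True,
    per_snp_n: bool = True,
) -> pd.DataFrame:
    """Per-SNP results table: s_hom/p_hom, s_het/p_het, weighted-Z baseline."""
    r = R.r if isinstance(R, CorrMatrix) else np.asarray(R, dtype=float)
    if isinstance(R, CorrMatrix) and [k.label for k in R.labels] != zp.labels:
        raise ValueError("correlation matrix labels do not match panel columns")
    if per_snp_n and np.isfinite(zp.n).any():
        n = np.where(np.isfinite(zp.n), zp.n, [float(k.n_max) for k in zp.columns])
    else:
        n = np.asarray([float(k.n_max) for k in zp.columns])

    out = zp.snps[["snp_id", "chromosome", "position"]].copy()
    s, p, used = s_hom_batch(zp.z, n, r, scheme)
    out["s_hom"] = s
    out["p_hom"] = p
    out["n_panels_used"] = used
    zc, pc = weighted_z_batch(zp.z, n)
    out["z_meta"] = zc
    out["p_meta"] = pc
    if compute_het:
        sh, tau, _ = s_het_batch(zp.z, n, r, scheme)
        out["s_het"] = sh
        out["tau_star"] = tau
        out["p_het"] = p_het_batch(sh, het_null) if het_null is not None else np.nan
    return out


def scan_summary(
    results: pd.DataFrame, method: str, threshold: float = GENOME_WIDE_P
) -> ScanSummary:
    col = {"s_hom": "p_hom", "s_het": "p_het", "weighted_z": "p_meta"}[method]
    p = results[col].to_numpy(dtype=float)
    finite = p[np.isfinite(p)]
    return ScanSummary(
        method=method,
        lambda_gc=genomic_control_lambda(finite, kind="p"),
        n_snps=int(finite.size),
        n_significant=int((finite < threshold).sum()),
        threshold=threshold,
    )


def identify_loci(
    results: pd.DataFrame,
    p_col: str,
    threshold: float = GENOME_WIDE_P,
    flank: int = DEFAULT_FLANK,
) -> list[Locus]:
    """Greedy clumping: smallest-p significant SNP leads a locus covering
    +-flank on its chromosome; assigned SNPs are removed and the process
    repeats.  Ties break by (chromosome, position)."""
    df = results.loc[
        np.isfinite(results[p_col]) & (results[p_col] < threshold),
        ["snp_id", "chromosome", "position", p_col],
    ].copy()
    loci: list[Locus] = []
    df = df.sort_values(
        [p_col, "chromosome", "position"], kind="mergesort"
    ).reset_index(drop=True)
    remaining = df
    while not remaining.empty:
        lead = remaining.iloc[0]
        in_window = (remaining["chromosome"] == lead["chromosome"]) & (
            (remaining["position"] - lead["position"]).abs() <= flank
        )
        members = remaining.loc[in_window]
        loci.append(
            Locus(
                lead_snp=str(lead["snp_id"]),
                chromosome=str(lead["chromosome"]),
                position=int(lead["position"]),
                lead_p=float(lead[p_col]),
                window_start=int(lead["position"]) - flank,
                window_end=int(lead["position"]) + flank,
                member_snps=[str(s) for s in members["snp_id"]],
            )
        )
        remaining = remaining.loc[~in_window]
    return loci


def novel_vs_baseline(
    candidate_loci: Sequence[Locus],
    baseline_results: pd.DataFrame,
    threshold: float = GENOME_WIDE_P,
    p_col: str = "p_meta",
    flank: int = DEFAULT_FLANK,
    ld_pairs: Iterable[tuple[str, str]] | None = None,
) -> list[Locus]:
    """Flag loci with no baseline-significant SNP in the 1.0 Mb region
    (lead +- flank) and, when supplied, no LD link to a baseline index SNP."""
    sig = baseline_results.loc[
        np.isfinite(baseline_results[p_col]) & (baseline_results[p_col] < threshold)
    ]
    linked = set()
    if ld_pairs is not None:
        for a, b in ld_pairs:
            linked.add((a, b))
            linked.add((b, a))
    base_ids = set(sig["snp_id"].astype(str))
    for locus in candidate_loci:
        near = sig.loc[
            (sig["chromosome"].astype(str) == locus.chromosome)
            & ((sig["position"] - locus.position).abs() <= flank)
        ]
        novel = near.empty
        if novel and linked:
            novel = not any((locus.lead_snp, b) in linked for b in base_ids)
        locus.novel_vs_baseline = bool(novel)
    return list(candidate_loci)


@dataclass
class CrossTab:
    """Locus-level agreement between two scans."""

    a_with_counterpart: int
    a_only: int
    b_with_counterpart: int
    b_only: int

    @property
    def a_total(self) -> int:
        return self.a_with_counterpart + self.a_only

    @property
    def b_total(self) -> int:
        return self.b_with_counterpart + self.b_only

    def to_frame(self, a: str = "method_a", b: str = "method_b") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": [a, a, b, b],
                "category": ["shared", "only", "shared", "only"],
                "n_loci": [
                    self.a_with_counterpart,
                    self.a_only,
                    self.b_with_counterpart,
                    self.b_only,
                ],
            }
        )


def _has_counterpart(locus: Locus, others: Sequence[Locus], flank: int) -> bool:
    return any(
        o.chromosome == locus.chromosome and abs(o.position - locus.position) <= flank
        for o in others
    )


def cross_tabulate(
    loci_a: Sequence[Locus],
    loci_b: Sequence[Locus],
    n_snps_a: int | None = None,
    n_snps_b: int | None = None,
    flank: int = DEFAULT_FLANK,
) -> CrossTab:
    """Classify each method's loci by whether the other method has a
    significant locus within the 1.0 Mb region (lead +- flank)."""
    if n_snps_a is not None and n_snps_b is not None and n_snps_a != n_snps_b:
        raise ValueError("scans cover different SNP sets")
    a_shared = sum(_has_counterpart(l, loci_b, flank) for l in loci_a)
    b_shared = sum(_has_counterpart(l, loci_a, flank) for l in loci_b)
    return CrossTab(
        a_with_counterpart=a_shared,
        a_only=len(loci_a) - a_shared,
        b_with_counterpart=b_shared,
        b_only=len(loci_b) - b_shared,
    )


def forest_data(zp: ZPanel, snp_ids: Sequence[str]) -> pd.DataFrame:
    """Long-format per-panel effect sizes for forest plotting."""
    if zp.beta is None:
        raise ValueError("panel carries no effect sizes (p_sign-only input)")
    idx = {s: i for i, s in enumerate(zp.snps["snp_id"])}
    rows = []
    for snp in snp_ids:
        if snp not in idx:
            raise KeyError(f"SNP {snp!r} not present in panel")
        i = idx[snp]
        for j, key in enumerate(zp.columns):
            b = zp.beta[i, j]
            if not np.isfinite(b):
                continue
            s = zp.se[i, j] if zp.se is not None else float("nan")
            rows.append(
                {
                    "snp_id": snp,
                    "cohort_id": key.cohort_id,
                    "trait_id": key.trait_id,
                    "beta": float(b),
                    "se": float(s),
                    "se_missing": not np.isfinite(s),
                    "n": float(zp.n[i, j]),
                }
            )
    return pd.DataFrame(rows)


def qq_data(p_values) -> pd.DataFrame:
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[np.isfinite(p)]
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(np.clip(p, np.nextafter(0, 1), 1.0))
    return pd.DataFrame({"expected_neglog10p": expected, "observed_neglog10p": observed})


def manhattan_data(results: pd.DataFrame, p_col: str) -> pd.DataFrame:
    """Cumulative plotting coordinates across chromosomes."""
    df = results[["snp_id", "chromosome", "position", p_col]].copy()

    def ckey(c: str):
        try:
            return int(c)
        except ValueError:
            return 1000

    df["_ckey"] = df["chromosome"].map(ckey)
    df = df.sort_values(["_ckey", "position"], kind="mergesort")
    offset = 0
    coords = np.empty(len(df))
    pos = df["position"].to_numpy()
    start = 0
    for _, grp in df.groupby("_ckey", sort=True):
        k = len(grp)
        coords[start : start + k] = pos[start : start + k] + offset
        offset = coords[start + k - 1]
        start += k
    df["genome_coord"] = coords
    df["neglog10p"] = -np.log10(np.clip(df[p_col], np.nextafter(0, 1), 1.0))
    return df.drop(columns="_ckey")
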