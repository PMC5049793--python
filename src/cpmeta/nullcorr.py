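"""Null-SNP selection and estimation of the between-panel correlation matrix.

The combined statistics need the correlation ``R`` of the panel Z scores
under the null, which is induced by overlapping samples and correlated
traits.  ``R`` is estimated from approximately independent SNPs (greedy LD
pruning at r^2 < 0.2) whose statistics are null-like (|Z| <= 1.96 in every
panel).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .sumstats import PanelKey, ZPanel

__all__ = [
    "PruneConfig",
    "CorrMatrix",
    "NullSelection",
    "EmptyNullSetError",
    "InsufficientOverlapError",
    "ld_prune",
    "select_null_snps",
    "estimate_corr",
    "nearest_psd",
]

log = logging.getLogger(__name__)


class EmptyNullSetError(ValueError):
    """The null-SNP filter removed every row."""


class InsufficientOverlapError(ValueError):
    """A panel pair shares too few non-missing null SNPs."""


@dataclass(frozen=True)
class PruneConfig:
    r2_threshold: float = 0.2
    window_snps: int = 50
    step_snps: int = 5
    z_cut: float = 1.96

    def __post_init__(self) -> None:
        if not (0 < self.r2_threshold < 1):
            raise ValueError("r2_threshold must be in (0, 1)")
        if self.z_cut <= 0:
            raise ValueError("z_cut must be positive")
        if self.window_snps < 2 or self.step_snps < 1:
            raise ValueError("invalid window/step")


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 2:
        return 0.0
    xs, ys = x[mask], y[mask]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.corrcoef(xs, ys)[0, 1])
    return r * r


def ld_prune(
    genotypes: np.ndarray,
    snp_positions: Sequence[int] | None = None,
    cfg: PruneConfig | None = None,
    snp_ids: Sequence[str] | None = None,
) -> list:
    """Greedy sliding-window LD pruning on a samples x SNPs dosage matrix.

    SNPs are scanned left to right in position order; within each window
    of ``window_snps`` markers (advanced by ``step_snps``) the later member
    of any pair with squared correlation >= ``r2_threshold`` is dropped.
    Monomorphic SNPs are excluded up front.  Returns the retained SNP ids
    (or integer indices when ``snp_ids`` is not given).
    """
    cfg = cfg or PruneConfig()
    geno = np.asarray(genotypes, dtype=float)
    if geno.ndim != 2 or geno.shape[1] < 2:
        raise ValueError("need a samples x SNPs matrix with >= 2 SNPs")
    m = geno.shape[1]
    ids: Sequence = snp_ids if snp_ids is not None else list(range(m))
    if len(ids) != m:
        raise ValueError("snp_ids length mismatch")
    if snp_positions is not None:
        order = np.argsort(np.asarray(snp_positions), kind="mergesort")
    else:
        order = np.arange(m)

    variances = np.nanvar(geno, axis=0)
    poly = [i for i in order if variances[i] > 0]
    n_mono = m - len(poly)
    if n_mono:
        log.info("ld_prune: excluded %d monomorphic SNPs", n_mono)

    kept = np.ones(len(poly), dtype=bool)
    start = 0
    while True:
        stop = min(start + cfg.window_snps, len(poly))
        window = [w for w in range(start, stop) if kept[w]]
        for a_pos, a in enumerate(window):
            if not kept[a]:
                continue
            for b in window[a_pos + 1 :]:
                if not kept[b]:
                    continue
                r2 = _pairwise_r2(geno[:, poly[a]], geno[:, poly[b]])
                if r2 >= cfg.r2_threshold:
                    kept[b] = False
        if stop >= len(poly):
            break
        start += cfg.step_snps
    return [ids[poly[i]] for i in np.flatnonzero(kept)]


class NullSelection(NamedTuple):
    zpanel: ZPanel
    n_kept: int
    per_panel_pass: dict


def select_null_snps(zp: ZPanel, retained: Iterable[str] | None, z_cut: float = 1.96) -> NullSelection:
    """Restrict a ZPanel to pruned SNPs that look null in every panel.

    A row survives only when every non-missing |Z| is <= ``z_cut``
    (boundary inclusive).  ``retained`` is the pruned SNP id list; pass
    None to skip the pruning restriction.
    """
    if retained is not None:
        wanted = set(retained)
        ids = set(zp.snps["snp_id"])
        missing = wanted - ids
        if missing:
            raise ValueError(f"{len(missing)} retained ids absent from panel (e.g. {sorted(missing)[:3]})")
        zp = zp.subset_by_ids(wanted)
    finite = np.isfinite(zp.z)
    passing = finite & (np.abs(zp.z) <= z_cut)
    row_ok = np.where(finite, passing, True).all(axis=1) & finite.any(axis=1)
    per_panel = {
        key.label: int(passing[:, j].sum()) for j, key in enumerate(zp.columns)
    }
    if not row_ok.any():
        raise EmptyNullSetError(
            "no SNP passed the null filter in all panels; supply more input SNPs"
        )
    sub = zp.subset_rows(row_ok)
    return NullSelection(zpanel=sub, n_kept=sub.n_snps, per_panel_pass=per_panel)


def nearest_psd(mat: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone by eigenvalue clipping,
    then rescale back to unit diagonal."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    fixed = vecs @ np.diag(np.clip(vals, 0.0, None)) @ vecs.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-300, None))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


@dataclass
class CorrMatrix:
    """Correlation of panel test statistics under the null."""

    labels: list[PanelKey]
    r: np.ndarray
    n_snps_used: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    psd_adjusted: bool = False

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        p = self.r.shape[0]
        if self.r.shape != (p, p) or len(self.labels) != p:
            raise ValueError("inconsistent CorrMatrix dimensions")
        if self.n_snps_used.size == 0:
            self.n_snps_used = np.zeros((p, p), dtype=int)

    @property
    def size(self) -> int:
        return self.r.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.r).min())

    def write(self, path: str | Path) -> None:
        path = Path(path)
        tags = [f"{k.cohort_id}|{k.trait_id}|{k.n_max}" for k in self.labels]
        df = pd.DataFrame(self.r, index=tags, columns=tags)
        df.to_csv(path, sep="\t", float_format="%.17g", index_label="panel")
        sidecar = {
            "labels": tags,
            "n_snps_used": self.n_snps_used.tolist(),
            "psd_adjusted": self.psd_adjusted,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "CorrMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        labels = []
        for tag in df.columns:
            cohort, trait, nmax = tag.split("|")
            labels.append(PanelKey(cohort, trait, int(nmax)))
        sidecar_path = path.with_suffix(path.suffix + ".json")
        n_used = np.zeros((len(labels), len(labels)), dtype=int)
        psd = False
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            n_used = np.asarray(meta.get("n_snps_used", n_used), dtype=int)
            psd = bool(meta.get("psd_adjusted", False))
        return cls(labels=labels, r=df.to_numpy(), n_snps_used=n_used, psd_adjusted=psd)


def truncation_attenuation(z_cut: float) -> float:
    """Attenuation of the Pearson correlation caused by the |Z| <= z_cut
    filter: for small true correlation rho, the doubly truncated sample
    correlation has expectation ~= rho * v with
    v = 1 - 2c*phi(c) / (2*Phi(c) - 1)."""
    c = float(z_cut)
    p0 = 2.0 * _stats.norm.cdf(c) - 1.0
    return 1.0 - 2.0 * c * _stats.norm.pdf(c) / p0


def estimate_corr(
    zp_null: ZPanel,
    min_pairs: int = 30,
    complete_case: bool = False,
    z_cut: float | None = None,
) -> CorrMatrix:
    """Pairwise-complete Pearson correlation of the null Z columns.

    Unit diagonal is imposed; if the result has a negative eigenvalue it is
    projected to the nearest PSD correlation matrix and flagged.

    When the rows were pre-filtered with :func:`select_null_snps`, pass the
    same ``z_cut`` here to undo the truncation attenuation (the raw Pearson
    estimate shrinks toward zero by a factor of ~0.76 at z_cut = 1.96, so
    the planted correlation cannot be recovered without this correction).
    """
    if zp_null.n_panels < 2:
        raise ValueError("need at least two panels")
    z = zp_null.z
    if complete_case:
        z = z[np.isfinite(z).all(axis=1)]
    p = z.shape[1]
    finite = np.isfinite(z)
    r = np.eye(p)
    counts = np.zeros((p, p), dtype=int)
    np.fill_diagonal(counts, finite.sum(axis=0))
    for i in range(p):
        for j in range(i + 1, p):
            mask = finite[:, i] & finite[:, j]
            c = int(mask.sum())
            counts[i, j] = counts[j, i] = c
            if c < min_pairs:
                raise InsufficientOverlapError(
                    f"panels {zp_null.columns[i].label} and {zp_null.columns[j].label} "
                    f"share only {c} null SNPs (< {min_pairs})"
                )
            rij = float(np.corrcoef(z[mask, i], z[mask, j])[0, 1])
            if z_cut is not None:
                rij /= truncation_attenuation(z_cut)
            r[i, j] = r[j, i] = np.clip(rij, -1.0, 1.0)

    psd_adjusted = False
    if np.linalg.eigvalsh(r).min() < -1e-10:
        warnings.warn("estimated correlation not PSD; applying eigenvalue clipping")
        r = nearest_psd(r)
        psd_adjusted = True
    return CorrMatrix(
        labels=list(zp_null.columns), r=r, n_snps_used=counts, psd_adjusted=psd_adjusted
    )
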