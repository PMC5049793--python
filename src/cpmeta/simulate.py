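"""Synthetic multi-cohort, multi-trait summary-statistic panels with known truth.

Statistics are simulated directly at the Z level: null rows are drawn
MVN(0, R_true), causal rows get a mean shift ``sqrt(n_j) * b * delta`` per
panel, and betas/ses are back-filled so that ``beta/se`` inverts to the
simulated Z exactly.  A small block-correlated genotype simulator is
provided as an LD-pruning fixture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sumstats import PanelKey, ZPanel

__all__ = [
    "CausalSpec",
    "SimConfig",
    "simulate_zpanel",
    "simulate_genotypes",
    "write_panel_files",
]

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "T"), ("C", "A")]


@dataclass(frozen=True)
class CausalSpec:
    """One planted causal SNP: panel pattern vector b and effect size delta."""

    snp_index: int
    pattern: tuple
    delta: float

    def label(self, j_cohorts: int) -> str:
        b = np.asarray(self.pattern, dtype=float)
        if self.delta == 0 or not b.any():
            return "null"
        nz = b[b != 0]
        if np.all(b == b[0]):
            return "homogeneous"
        # cohort-specific: non-zero entries confined to one cohort slot
        cohort_of = np.arange(b.size) % j_cohorts
        if len(set(cohort_of[b != 0])) == 1:
            return "sex_specific"
        if np.all(nz == nz[0]) and (b == 0).any():
            return "sex_specific"
        return "heterogeneous"


@dataclass
class SimConfig:
    J: int
    K: int
    M: int
    n: Sequence[float]
    R_true: np.ndarray
    causal: list[CausalSpec] = field(default_factory=list)
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    cohort_ids: Sequence[str] | None = None
    trait_ids: Sequence[str] | None = None
    position_spacing: int = 50_000

    def __post_init__(self) -> None:
        self.R_true = np.atleast_2d(np.asarray(self.R_true, dtype=float))
        p = self.J * self.K
        if self.R_true.shape != (p, p):
            raise ValueError("R_true must be (J*K) x (J*K)")
        if not np.allclose(self.R_true, self.R_true.T):
            raise ValueError("R_true must be symmetric")
        if not np.allclose(np.diag(self.R_true), 1.0):
            raise ValueError("R_true must have unit diagonal")
        if np.linalg.eigvalsh(self.R_true).min() < -1e-10:
            raise ValueError("R_true is not positive semi-definite")
        if len(self.n) != self.J:
            raise ValueError("need one sample size per cohort")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for c in self.causal:
            if not (0 <= c.snp_index < self.M):
                raise ValueError("causal snp_index out of range")
            if len(c.pattern) != p:
                raise ValueError("causal pattern length must be J*K")
            if c.delta < 0:
                raise ValueError("delta must be >= 0")

    @property
    def panel_keys(self) -> list[PanelKey]:
        cohorts = list(self.cohort_ids or _default_cohorts(self.J))
        traits = list(self.trait_ids or [f"trait{k+1}" for k in range(self.K)])
        # cohort index varies fastest within each trait block
        return [
            PanelKey(cohorts[j], traits[k], int(self.n[j]))
            for k in range(self.K)
            for j in range(self.J)
        ]


def _default_cohorts(j: int) -> list[str]:
    if j == 2:
        return ["males", "females"]
    return [f"cohort{i+1}" for i in range(j)]


def _snp_metadata(cfg: SimConfig) -> pd.DataFrame:
    m = cfg.M
    chroms = 1 + (np.arange(m) * 22) // m
    pos = np.empty(m, dtype=int)
    for c in range(1, 23):
        mask = chroms == c
        pos[mask] = (np.arange(mask.sum()) + 1) * cfg.position_spacing
    pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(m)]
    return pd.DataFrame(
        {
            "snp_id": [f"snp{c}_{p}" for c, p in zip(chroms, pos)],
            "chromosome": chroms.astype(str),
            "position": pos,
            "effect_allele": [ea for ea, _ in pairs],
            "other_allele": [oa for _, oa in pairs],
        }
    )


def simulate_zpanel(cfg: SimConfig) -> tuple[ZPanel, pd.DataFrame]:
    """Draw the panel and its ground truth table.

    Returns ``(zpanel, truth)`` where ``truth`` has one row per SNP with
    the causal flag, the pattern label and the per-panel noncentrality.
    """
    rng = np.random.default_rng(cfg.seed)
    p = cfg.J * cfg.K
    chol = np.linalg.cholesky(cfg.R_true + 1e-12 * np.eye(p))
    z = rng.standard_normal((cfg.M, p)) @ chol.T

    n_panel = np.array([float(k.n_max) for k in cfg.panel_keys])
    mean = np.zeros((cfg.M, p))
    labels = np.full(cfg.M, "null", dtype=object)
    for spec in cfg.causal:
        shift = np.sqrt(n_panel) * np.asarray(spec.pattern, dtype=float) * spec.delta
        mean[spec.snp_index] += shift
        labels[spec.snp_index] = spec.label(cfg.J)
    z = z + mean

    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, size=cfg.M)
    nmat = np.broadcast_to(n_panel, (cfg.M, p)).copy()
    denom = np.sqrt(2.0 * maf[:, None] * (1.0 - maf[:, None]) * nmat)
    se = 1.0 / denom
    beta = z * se

    snps = _snp_metadata(cfg)
    zp = ZPanel(snps=snps, columns=cfg.panel_keys, z=z, n=nmat, beta=beta, se=se)
    truth = snps[["snp_id", "chromosome", "position"]].copy()
    truth["causal"] = labels != "null"
    truth["pattern"] = labels
    truth["maf"] = maf
    for j, key in enumerate(cfg.panel_keys):
        truth[f"ncp:{key.label}"] = mean[:, j]
    return zp, truth


def simulate_genotypes(
    n_samples: int,
    blocks: Sequence[tuple[int, float]],
    maf: float = 0.3,
    seed: int = 0,
    spacing: int = 5_000,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Block-exchangeable correlated dosages for LD-pruning fixtures.

    Each block is ``(n_snps, within_block_r)``: haplotype alleles copy a
    shared block ancestor with probability sqrt(r), giving pairwise
    dosage correlation ~= r within the block and independence across
    blocks.  Returns (dosages, positions, snp_ids).
    """
    if not (0 < maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    cols, ids = [], []
    snp_counter = 0
    for bi, (n_snps, r) in enumerate(blocks):
        if not (0 <= r < 1):
            raise ValueError("within-block r must be in [0, 1)")
        copy_p = np.sqrt(r)
        for _hap in range(2):
            anc = rng.random(n_samples) < maf  # block ancestor per haplotype
            use_anc = rng.random((n_samples, n_snps)) < copy_p
            fresh = rng.random((n_samples, n_snps)) < maf
            hap = np.where(use_anc, anc[:, None], fresh)
            if _hap == 0:
                block_dos = hap.astype(np.int8)
            else:
                block_dos = block_dos + hap.astype(np.int8)
        cols.append(block_dos)
        ids.extend(f"b{bi}_s{k}" for k in range(n_snps))
        snp_counter += n_snps
    geno = np.concatenate(cols, axis=1).astype(float)
    positions = (np.arange(snp_counter) + 1) * spacing
    return geno, positions, ids


def write_panel_files(
    zp: ZPanel,
    outdir: str | Path,
    truth: pd.DataFrame | None = None,
    r_true: np.ndarray | None = None,
    seed: int | None = None,
) -> dict:
    """Write per-panel summary files plus truth and manifest (simulate CLI)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"panels": {}, "seed": seed}
    from scipy import stats as _st

    for j, key in enumerate(zp.columns):
        obs = np.isfinite(zp.z[:, j])
        df = zp.snps.loc[obs, :].copy()
        df.columns = ["SNP", "CHR", "POS", "EA", "OA"]
        df["EAF"] = 0.5  # placeholder when no per-SNP frequency tracked
        if zp.beta is not None:
            df["BETA"] = zp.beta[obs, j]
            df["SE"] = zp.se[obs, j]
        else:
            df["BETA"] = zp.z[obs, j]
            df["SE"] = 1.0
        pvals = 2.0 * _st.norm.sf(np.abs(zp.z[obs, j]))
        df["P"] = np.clip(pvals, np.nextafter(0, 1), 1.0)
        df["N"] = zp.n[obs, j]
        fname = outdir / f"panel_{key.cohort_id}_{key.trait_id}.tsv"
        df.to_csv(fname, sep="\t", index=False, float_format="%.17g")
        manifest["panels"][key.label] = {"path": str(fname), "n_max": key.n_max}
    if truth is not None:
        tpath = outdir / "truth.tsv"
        truth.to_csv(tpath, sep="\t", index=False, float_format="%.17g")
        manifest["truth"] = str(tpath)
    if r_true is not None:
        rpath = outdir / "r_true.tsv"
        pd.DataFrame(r_true).to_csv(rpath, sep="\t", index=False, header=False)
        manifest["r_true"] = str(rpath)
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return manifest
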