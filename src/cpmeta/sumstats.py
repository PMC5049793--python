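"""Reading, validation and allele harmonisation of GWAS summary statistics.

Per-panel (cohort x trait) association results are ingested from
whitespace/tab-delimited files, validated record by record, and aligned onto
a single reference effect allele per SNP so that the signs of the Z scores
are comparable across panels.  The aligned panel is held in a :class:`ZPanel`
and can be round-tripped through a plain TSV interchange format.
"""

from __future__ import annotations

import dataclasses
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryRecord",
    "PanelKey",
    "ZPanel",
    "ReadResult",
    "DialectError",
    "HarmonizeError",
    "DEFAULT_DIALECT",
    "GIANT_DIALECT",
    "read_sumstats",
    "z_from_record",
    "harmonize",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")
_AUTOSOMES = frozenset(str(i) for i in range(1, 23))

#: canonical field -> column header used by this package's own writers
DEFAULT_DIALECT: dict[str, str] = {
    "snp_id": "SNP",
    "chromosome": "CHR",
    "position": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "p_value": "P",
    "n": "N",
}

#: historical GIANT-consortium column names
GIANT_DIALECT: dict[str, str] = {
    "snp_id": "MarkerName",
    "chromosome": "Chr",
    "position": "Pos",
    "effect_allele": "Allele1",
    "other_allele": "Allele2",
    "eaf": "Freq.Allele1.HapMapCEU",
    "beta": "b",
    "se": "SE",
    "p_value": "p",
    "n": "N",
}

_MANDATORY = (
    "snp_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "p_value",
)
_OPTIONAL = ("eaf", "n")


class DialectError(ValueError):
    """A mandatory column is missing from the input header."""


class HarmonizeError(ValueError):
    """Panels could not be aligned (e.g. empty SNP intersection)."""


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association evidence in one cohort-trait panel."""

    snp_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p_value: float
    n: float

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: identical alleles")
        if not (self.se > 0):
            raise ValueError(f"{self.snp_id}: se must be > 0")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"{self.snp_id}: p outside (0, 1]")
        if not (math.isnan(self.eaf) or 0 <= self.eaf <= 1):
            raise ValueError(f"{self.snp_id}: eaf outside [0, 1]")
        if self.n < 1:
            raise ValueError(f"{self.snp_id}: n < 1")


@dataclass(frozen=True)
class PanelKey:
    """Identifies one cohort x trait panel."""

    cohort_id: str
    trait_id: str
    n_max: int = 0

    @property
    def label(self) -> str:
        return f"{self.cohort_id}:{self.trait_id}"


@dataclass
class ReadResult:
    records: list[SummaryRecord]
    rejects: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _chrom_sort_value(chrom: str) -> int:
    try:
        return int(chrom)
    except ValueError:
        return 1000 + (ord(chrom[0]) if chrom else 0)


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    default_n: float | None = None,
) -> ReadResult:
    """Read one panel's summary statistics file.

    ``dialect`` maps canonical field names to the column headers present in
    the file.  Malformed data lines are rejected (not fatal) and reported
    with their 1-based line numbers.  Records come back sorted by
    (chromosome, position).

    Raises :class:`DialectError` if a mandatory mapped column is absent.
    """
    dialect = dict(dialect or DEFAULT_DIALECT)
    df = pd.read_csv(path, sep=r"\s+", dtype=str, comment="#")
    for fld in _MANDATORY:
        col = dialect.get(fld)
        if col is None or col not in df.columns:
            raise DialectError(f"mandatory column for '{fld}' ({col!r}) not in header")

    out = pd.DataFrame(index=df.index)
    out["snp_id"] = df[dialect["snp_id"]].astype(str)
    out["chromosome"] = df[dialect["chromosome"]].astype(str)
    out["position"] = pd.to_numeric(df[dialect["position"]], errors="coerce")
    out["effect_allele"] = df[dialect["effect_allele"]].str.upper()
    out["other_allele"] = df[dialect["other_allele"]].str.upper()
    for fld in ("beta", "se", "p_value"):
        out[fld] = pd.to_numeric(df[dialect[fld]], errors="coerce")
    for fld in _OPTIONAL:
        col = dialect.get(fld)
        if col is not None and col in df.columns:
            out[fld] = pd.to_numeric(df[col], errors="coerce")
        else:
            out[fld] = np.nan
    if default_n is not None:
        out["n"] = out["n"].fillna(default_n)

    reasons = pd.Series("", index=out.index)

    def flag(mask: pd.Series, why: str) -> None:
        nonlocal reasons
        reasons = reasons.mask(mask & (reasons == ""), why)

    flag(out["position"].isna() | (out["position"] < 1), "bad position")
    flag(~out["effect_allele"].isin(_VALID_ALLELES), "bad effect allele")
    flag(~out["other_allele"].isin(_VALID_ALLELES), "bad other allele")
    flag(out["effect_allele"] == out["other_allele"], "identical alleles")
    flag(out["beta"].isna(), "non-numeric beta")
    flag(out["se"].isna() | (out["se"] <= 0), "invalid se")
    flag(out["p_value"].isna() | (out["p_value"] <= 0) | (out["p_value"] > 1), "p outside (0,1]")
    flag(out["eaf"].notna() & ((out["eaf"] < 0) | (out["eaf"] > 1)), "eaf outside [0,1]")
    flag(out["n"].notna() & (out["n"] < 1), "n < 1")

    bad = reasons != ""
    # line numbers: +2 for the header line and 1-based counting
    rejects = [(int(i) + 2, why) for i, why in reasons[bad].items()]
    good = out[~bad].copy()
    good["n"] = good["n"].fillna(np.nan)
    good["_ckey"] = good["chromosome"].map(_chrom_sort_value)
    good = good.sort_values(["_ckey", "position"], kind="mergesort")

    records = [
        SummaryRecord(
            snp_id=r.snp_id,
            chromosome=r.chromosome,
            position=int(r.position),
            effect_allele=r.effect_allele,
            other_allele=r.other_allele,
            eaf=float(r.eaf) if pd.notna(r.eaf) else float("nan"),
            beta=float(r.beta),
            se=float(r.se),
            p_value=float(r.p_value),
            n=float(r.n) if pd.notna(r.n) else float("nan"),
        )
        for r in good.itertuples(index=False)
    ]
    return ReadResult(records=records, rejects=rejects)


def z_from_record(rec: SummaryRecord, mode: str = "beta_se") -> float:
    """Wald Z (beta/se) or the signed normal quantile reconstructed from p.

    ``p_sign`` mode returns ``sign(beta) * Phi^{-1}(1 - p/2)`` using the
    two-sided convention; ``p = 1`` maps to 0.
    """
    if mode == "beta_se":
        if not rec.se > 0:
            raise ValueError("beta_se mode requires se > 0")
        return rec.beta / rec.se
    if mode == "p_sign":
        if rec.p_value <= 0:
            raise ValueError("p_sign mode requires p > 0")
        mag = float(stats.norm.isf(rec.p_value / 2.0))
        return math.copysign(mag, rec.beta) if rec.beta != 0 else mag
    raise ValueError(f"unknown mode {mode!r}")


def _records_to_frame(records: Iterable[SummaryRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows)
    return df.drop_duplicates(subset="snp_id", keep="first")


def _is_ambiguous(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return ea == oa.map(_COMPLEMENT)


@dataclass
class ZPanel:
    """SNP x panel matrix of harmonized test statistics.

    ``snps`` holds the row metadata (snp_id, chromosome, position and the
    reference effect/other alleles); ``z`` and ``n`` are (M, P) float arrays
    with NaN marking missing entries.  ``beta``/``se`` are optional and on
    the same reference-allele orientation as ``z``.
    """

    snps: pd.DataFrame
    columns: list[PanelKey]
    z: np.ndarray
    n: np.ndarray
    beta: np.ndarray | None = None
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        self.z = np.asarray(self.z, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        m, p = self.z.shape
        if len(self.snps) != m or len(self.columns) != p:
            raise ValueError("inconsistent ZPanel dimensions")

    @property
    def n_snps(self) -> int:
        return self.z.shape[0]

    @property
    def n_panels(self) -> int:
        return self.z.shape[1]

    @property
    def labels(self) -> list[str]:
        return [k.label for k in self.columns]

    def subset_rows(self, mask_or_idx) -> "ZPanel":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ZPanel(
            snps=self.snps.iloc[idx],
            columns=list(self.columns),
            z=self.z[idx],
            n=self.n[idx],
            beta=None if self.beta is None else self.beta[idx],
            se=None if self.se is None else self.se[idx],
        )

    def subset_by_ids(self, snp_ids: Iterable[str]) -> "ZPanel":
        wanted = set(snp_ids)
        mask = self.snps["snp_id"].isin(wanted).to_numpy()
        return self.subset_rows(mask)

    # ---- interchange TSV ------------------------------------------------

    def write(self, path: str | Path) -> None:
        df = self.snps.copy()
        for j, key in enumerate(self.columns):
            tag = f"{key.cohort_id}|{key.trait_id}|{key.n_max}"
            df[f"z:{tag}"] = self.z[:, j]
            df[f"n:{tag}"] = self.n[:, j]
            if self.beta is not None:
                df[f"beta:{tag}"] = self.beta[:, j]
            if self.se is not None:
                df[f"se:{tag}"] = self.se[:, j]
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read(cls, path: str | Path) -> "ZPanel":
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str}, float_precision="round_trip")
        meta_cols = ["snp_id", "chromosome", "position", "effect_allele", "other_allele"]
        tagre = re.compile(r"^(z|n|beta|se):(.+)\|(.+)\|(\d+)$")
        tags: list[tuple[str, str, int]] = []
        for col in df.columns:
            m = tagre.match(col)
            if m and m.group(1) == "z":
                tags.append((m.group(2), m.group(3), int(m.group(4))))
        columns = [PanelKey(c, t, n) for c, t, n in tags]
        z = np.column_stack([df[f"z:{c}|{t}|{n}"] for c, t, n in tags])
        nmat = np.column_stack([df[f"n:{c}|{t}|{n}"] for c, t, n in tags])
        beta = se = None
        if all(f"beta:{c}|{t}|{n}" in df.columns for c, t, n in tags):
            beta = np.column_stack([df[f"beta:{c}|{t}|{n}"] for c, t, n in tags])
        if all(f"se:{c}|{t}|{n}" in df.columns for c, t, n in tags):
            se = np.column_stack([df[f"se:{c}|{t}|{n}"] for c, t, n in tags])
        return cls(snps=df[meta_cols], columns=columns, z=z, n=nmat, beta=beta, se=se)


def harmonize(
    panels: Mapping[PanelKey, Sequence[SummaryRecord]],
    drop_ambiguous: bool = True,
    policy: str = "intersection",
    z_mode: str = "beta_se",
    autosomes_only: bool = True,
) -> ZPanel:
    """Align panels onto a per-SNP reference effect allele.

    The reference orientation is taken from the first panel carrying each
    SNP.  A panel whose alleles are swapped relative to the reference
    contributes ``-Z`` (and ``-beta``); strand (complement) flips are
    attempted before a SNP is declared mismatched for that panel.  A/T and
    C/G SNPs are removed when ``drop_ambiguous`` is set.  ``policy`` is
    ``"intersection"`` (row kept only if observed in every panel) or
    ``"union"``.
    """
    if not panels:
        raise HarmonizeError("no panels supplied")
    if policy not in ("intersection", "union"):
        raise ValueError(f"unknown policy {policy!r}")

    frames = {key: _records_to_frame(recs) for key, recs in panels.items()}
    for key, df in frames.items():
        if df.empty:
            raise HarmonizeError(f"panel {key.label} contains no records")

    ref = (
        pd.concat(frames.values(), ignore_index=True)
        .drop_duplicates(subset="snp_id", keep="first")
        .loc[:, ["snp_id", "chromosome", "position", "effect_allele", "other_allele"]]
        .set_index("snp_id")
    )
    if autosomes_only:
        ref = ref[ref["chromosome"].isin(_AUTOSOMES)]
    if drop_ambiguous:
        ref = ref[~_is_ambiguous(ref["effect_allele"], ref["other_allele"])]
    if ref.empty:
        raise HarmonizeError("no usable SNPs after filtering")

    keys = list(panels.keys())
    m = len(ref)
    p = len(keys)
    z = np.full((m, p), np.nan)
    nmat = np.full((m, p), np.nan)
    beta = np.full((m, p), np.nan)
    se = np.full((m, p), np.nan)

    for j, key in enumerate(keys):
        df = frames[key].set_index("snp_id").reindex(ref.index)
        ea, oa = df["effect_allele"], df["other_allele"]
        rea, roa = ref["effect_allele"], ref["other_allele"]
        cea, coa = ea.map(_COMPLEMENT), oa.map(_COMPLEMENT)
        sign = np.full(m, np.nan)
        sign[((ea == rea) & (oa == roa)) | ((cea == rea) & (coa == roa))] = 1.0
        sign[((ea == roa) & (oa == rea)) | ((cea == roa) & (coa == rea))] = -1.0

        if z_mode == "beta_se":
            zcol = df["beta"] / df["se"]
        elif z_mode == "p_sign":
            mag = stats.norm.isf(df["p_value"] / 2.0)
            zcol = np.sign(df["beta"]).replace(0, 1) * mag
        else:
            raise ValueError(f"unknown z_mode {z_mode!r}")
        z[:, j] = sign * zcol.to_numpy()
        beta[:, j] = sign * df["beta"].to_numpy()
        se[:, j] = df["se"].to_numpy()
        ncol = df["n"].to_numpy(dtype=float)
        ncol = np.where(np.isnan(ncol), float(key.n_max) if key.n_max else np.nan, ncol)
        nmat[:, j] = np.where(np.isfinite(z[:, j]), ncol, np.nan)

    observed = np.isfinite(z)
    keep = observed.all(axis=1) if policy == "intersection" else observed.any(axis=1)
    if not keep.any():
        raise HarmonizeError(
            "empty SNP intersection across panels: " + ", ".join(k.label for k in keys)
        )

    snps = ref.reset_index().loc[keep].reset_index(drop=True)
    order = np.lexsort((snps["position"].to_numpy(), snps["chromosome"].map(_chrom_sort_value).to_numpy()))
    snps = snps.iloc[order].reset_index(drop=True)
    sel = np.flatnonzero(keep)[order]
    return ZPanel(snps=snps, columns=keys, z=z[sel], n=nmat[sel], beta=beta[sel], se=se[sel])
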