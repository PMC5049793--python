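"""Run configuration and the end-to-end pipeline driver."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import nullcorr, scan, simulate, sumstats
from .combine import build_shet_null
from .sumstats import PanelKey

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything needed to reproduce one run.

    Either ``simulate`` (a SimConfig-shaped mapping) or ``panels`` (a list
    of {cohort_id, trait_id, n_max, path, dialect} mappings) must be
    given.  ``seed`` is mandatory whenever the heterogeneous statistic is
    requested because its p-values are Monte Carlo.
    """

    output_dir: str = "cpmeta_run"
    seed: int | None = None
    panels: list[dict] = field(default_factory=list)
    simulate: dict | None = None
    weight_scheme: str = "sqrt_n"
    z_cut: float = 1.96
    prune: dict = field(default_factory=dict)
    pruned_snp_list: str | None = None
    compute_het: bool = True
    het_null_draws: int = 100_000
    threshold_primary: float = 5e-8
    threshold_secondary: float = 1e-7
    flank: int = 500_000
    drop_ambiguous: bool = True
    missing_policy: str = "intersection"

    def validate(self) -> None:
        if self.simulate is None and not self.panels:
            raise ConfigError("either 'simulate' or 'panels' must be configured")
        if self.compute_het and self.seed is None:
            raise ConfigError("seed is mandatory when the heterogeneous statistic is requested")
        for thr in (self.threshold_primary, self.threshold_secondary):
            if not (0 < thr < 1):
                raise ConfigError("thresholds must lie in (0, 1)")
        if self.weight_scheme not in ("sqrt_n", "n", "unit"):
            raise ConfigError(f"unknown weight scheme {self.weight_scheme!r}")
        for spec in self.panels:
            path = spec.get("path")
            if path is None or not Path(path).exists():
                raise ConfigError(f"panel input path missing or absent: {path!r}")
        if self.pruned_snp_list is not None and not Path(self.pruned_snp_list).exists():
            raise ConfigError(f"pruned SNP list not found: {self.pruned_snp_list}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _build_sim_config(cfg: RunConfig) -> simulate.SimConfig:
    spec = dict(cfg.simulate or {})
    causal = [
        simulate.CausalSpec(int(c["snp_index"]), tuple(c["pattern"]), float(c["delta"]))
        for c in spec.pop("causal", [])
    ]
    r_true = np.asarray(spec.pop("R_true"), dtype=float)
    seed = spec.pop("seed", cfg.seed if cfg.seed is not None else 0)
    return simulate.SimConfig(causal=causal, R_true=r_true, seed=seed, **spec)


def _ingest_panels(cfg: RunConfig) -> sumstats.ZPanel:
    panels: dict[PanelKey, Any] = {}
    for spec in cfg.panels:
        key = PanelKey(spec["cohort_id"], spec["trait_id"], int(spec.get("n_max", 0)))
        dialect = spec.get("dialect")
        if dialect == "giant":
            dialect = sumstats.GIANT_DIALECT
        result = sumstats.read_sumstats(spec["path"], dialect=dialect, default_n=key.n_max or None)
        if result.n_rejected:
            log.warning("%s: %d records rejected", key.label, result.n_rejected)
        panels[key] = result.records
    return sumstats.harmonize(
        panels, drop_ambiguous=cfg.drop_ambiguous, policy=cfg.missing_policy
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute simulate/ingest -> harmonize -> estimate-R -> scan -> loci ->
    compare -> report; returns (and writes) the run manifest."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "stages": {},
        "artifacts": {},
        "status": "running",
    }
    mpath = outdir / "manifest.json"

    def artifact(name: str, path: Path) -> None:
        manifest["artifacts"][name] = str(path)

    def fail(stage: str, exc: Exception):
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        mpath.write_text(json.dumps(manifest, indent=1))
        raise

    stage = "input"
    try:
        if cfg.simulate is not None:
            sim_cfg = _build_sim_config(cfg)
            zp, truth = simulate.simulate_zpanel(sim_cfg)
            truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
            artifact("truth", outdir / "truth.tsv")
        else:
            zp = _ingest_panels(cfg)
        zp.write(outdir / "zpanel.tsv")
        artifact("zpanel", outdir / "zpanel.tsv")
        manifest["stages"][stage] = "ok"

        stage = "estimate_corr"
        retained = None
        if cfg.pruned_snp_list is not None:
            retained = [
                line.strip()
                for line in Path(cfg.pruned_snp_list).read_text().splitlines()
                if line.strip()
            ]
        null_sel = nullcorr.select_null_snps(zp, retained, z_cut=cfg.z_cut)
        corr = nullcorr.estimate_corr(null_sel.zpanel, z_cut=cfg.z_cut)
        corr.write(outdir / "corr.tsv")
        artifact("corr", outdir / "corr.tsv")
        manifest["stages"][stage] = "ok"
        manifest["n_null_snps"] = null_sel.n_kept

        stage = "scan"
        het_null = None
        if cfg.compute_het:
            n_vec = np.array([float(k.n_max) for k in zp.columns])
            het_null = build_shet_null(
                corr.r,
                n_vec,
                scheme=cfg.weight_scheme,
                B=cfg.het_null_draws,
                seed=cfg.seed,
                labels=zp.labels,
            )
            het_null.save(outdir / "shet")
            artifact("het_null", outdir / "shet.null.json")
        results = scan.run_scan(
            zp, corr, scheme=cfg.weight_scheme, het_null=het_null, compute_het=cfg.compute_het
        )
        results.to_csv(outdir / "results.tsv", sep="\t", index=False, float_format="%.10g")
        artifact("results", outdir / "results.tsv")
        manifest["stages"][stage] = "ok"

        stage = "loci"
        methods = ["s_hom", "weighted_z"] + (["s_het"] if cfg.compute_het else [])
        pcols = {"s_hom": "p_hom", "s_het": "p_het", "weighted_z": "p_meta"}
        all_loci = {}
        lambdas = {}
        for method in methods:
            summary = scan.scan_summary(results, method, cfg.threshold_primary)
            lambdas[method] = summary.lambda_gc
            for tier, thr in (("primary", cfg.threshold_primary), ("secondary", cfg.threshold_secondary)):
                loci = scan.identify_loci(results, pcols[method], thr, cfg.flank)
                if method != "weighted_z":
                    loci = scan.novel_vs_baseline(
                        loci, results, cfg.threshold_primary, "p_meta", cfg.flank
                    )
                all_loci[(method, tier)] = loci
                rows = [
                    {
                        "lead_snp": l.lead_snp,
                        "chromosome": l.chromosome,
                        "position": l.position,
                        "lead_p": l.lead_p,
                        "window_start": l.window_start,
                        "window_end": l.window_end,
                        "n_members": len(l.member_snps),
                        "members": ",".join(l.member_snps),
                        "novel_vs_baseline": l.novel_vs_baseline,
                    }
                    for l in loci
                ]
                lpath = outdir / f"loci_{method}_{tier}.tsv"
                import pandas as pd

                pd.DataFrame(
                    rows,
                    columns=[
                        "lead_snp",
                        "chromosome",
                        "position",
                        "lead_p",
                        "window_start",
                        "window_end",
                        "n_members",
                        "members",
                        "novel_vs_baseline",
                    ],
                ).to_csv(lpath, sep="\t", index=False)
                artifact(f"loci_{method}_{tier}", lpath)
        manifest["stages"][stage] = "ok"

        stage = "compare"
        for method in methods:
            if method == "weighted_z":
                continue
            tab = scan.cross_tabulate(
                all_loci[(method, "primary")],
                all_loci[("weighted_z", "primary")],
                len(results),
                len(results),
                cfg.flank,
            )
            cpath = outdir / f"crosstab_{method}.tsv"
            tab.to_frame(method, "weighted_z").to_csv(cpath, sep="\t", index=False)
            artifact(f"crosstab_{method}", cpath)
        manifest["stages"][stage] = "ok"

        stage = "report"
        (outdir / "lambda.json").write_text(json.dumps(lambdas, indent=1))
        artifact("lambda", outdir / "lambda.json")
        for method in methods:
            qq = scan.qq_data(results[pcols[method]].dropna())
            qq.to_csv(outdir / f"qq_{method}.tsv", sep="\t", index=False, float_format="%.6g")
            artifact(f"qq_{method}", outdir / f"qq_{method}.tsv")
        manifest["stages"][stage] = "ok"
        manifest["status"] = "complete"
        manifest["n_loci"] = {
            f"{m}_{t}": len(v) for (m, t), v in all_loci.items()
        }
        manifest["n_novel_primary"] = {
            m: sum(1 for l in all_loci[(m, "primary")] if l.novel_vs_baseline)
            for m in methods
            if m != "weighted_z"
        }
    except Exception as exc:  # noqa: BLE001 - manifest must record the failure
        fail(stage, exc)

    mpath.write_text(json.dumps(manifest, indent=1))
    return manifest
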