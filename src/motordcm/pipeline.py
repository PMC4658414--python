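"""End-to-end orchestration: synthesize-or-load -> behavior screen ->
invert -> QC -> post-hoc reduction -> group statistics -> clustering ->
covariate-adjusted correlations.

A single seed drives every stage through named sub-streams; re-running an
identical configuration reproduces every output table byte for byte.  The
run manifest records the seed, option and input hashes, package versions
and per-stage subject counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import read_press_log, score_log
from .clustering import cluster_parameters
from .cohort import CohortSpec, covariate_table, generate_cohort, write_cohort
from .generative import ROITimeSeries
from .inversion import QC_THRESHOLD_DEFAULT, default_priors, invert, qc_filter
from .network import count_connections, winning_model_preset, motor_network_preset
from .paradigm import StimulusDesign, build_paradigm, inputs_at_microtime, read_events_tsv
from .reduction import pooled_posthoc_search
from .stats import (
    ancova_per_connection,
    pairwise_posthoc,
    partial_correlation,
    results_frame,
)

KEY_CONNECTIONS = ("B:complexity:lPMd<-lSPC", "B:speed:pSMA<-rSPC", "B:speed:pSMA<-cSMA")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-serialisable)."""

    mode: str = "synthetic"  # "synthetic" | "files"
    input_dir: str | None = None  # for mode="files"
    seed: int = 0
    n_per_group: tuple[int, int, int] = (77, 62, 16)
    model: str = "winning"  # "winning" | "full"
    run_reduction: bool = False
    inversion_dt: float | None = 1.5
    max_iter: int = 32
    tol: float = 1e-2
    qc_threshold: float = QC_THRESHOLD_DEFAULT
    alpha: float = 0.05
    n_tests: int | None = 47
    covariates: tuple[str, ...] = ("age", "gender", "site", "education")
    k_max: int = 6
    zscore: bool = False
    outdir: str = "motordcm-out"
    write_inputs: bool = False
    quiet: bool = True

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        if cfg.mode == "synthetic" and "seed" not in data and "seed" not in overrides:
            raise ValueError("synthetic mode requires an explicit seed")
        return cfg

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.mode == "files" and not self.input_dir:
            raise ValueError("mode='files' requires input_dir")


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def read_subject_bundle(subject_dir, events_path=None):
    """Load one subject's (time series, design, press log, covariates).

    Raises with the offending file and line when a table is malformed.
    """
    sdir = Path(subject_dir)
    ts_path = sdir / "timeseries.csv"
    try:
        ts_df = pd.read_csv(ts_path)
    except pd.errors.ParserError as err:
        raise ValueError(f"{ts_path}: {err}") from err
    if ts_df.isna().any().any():
        bad = int(np.where(ts_df.isna().any(axis=1))[0][0]) + 2  # header + 1-base
        raise ValueError(f"{ts_path}: malformed or truncated row at line {bad}")
    meta = json.loads((sdir / "timeseries.json").read_text())
    ts = ROITimeSeries(
        data=ts_df.to_numpy(float), tr=float(meta["tr"]), labels=tuple(ts_df.columns)
    )
    events_path = events_path or (sdir.parent / "events.tsv")
    schedule = read_events_tsv(events_path)
    total = ts.data.shape[0] * ts.tr
    design = inputs_at_microtime(schedule, ts.tr / 16, total)
    press = None
    if (sdir / "presses.tsv").exists():
        press = read_press_log(sdir / "presses.tsv", design, subject_id=sdir.name)
    cov_path = sdir.parent / "covariates.csv"
    covs = None
    if cov_path.exists():
        table = pd.read_csv(cov_path)
        row = table[table.subject == sdir.name]
        covs = row.iloc[0].to_dict() if len(row) else None
    return ts, design, press, covs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "options_hash": _hash(asdict(config)),
        "stages": {},
    }
    net = winning_model_preset() if config.model == "winning" else motor_network_preset()
    manifest["model"] = {
        "name": config.model,
        "connections": count_connections(net),
    }

    stage = "synthesize" if config.mode == "synthetic" else "load"
    try:
        if config.mode == "synthetic":
            from .cohort import PlantedCluster

            n_pre = config.n_per_group[1]
            # planted sub-cluster scales with the pre-symptomatic pool
            # (9 of 62 in the full design)
            planted = PlantedCluster(size=max(0, round(9 * n_pre / 62)))
            spec = CohortSpec(
                n_per_group=tuple(config.n_per_group),
                planted_cluster=planted,
                seed=config.seed,
            )
            design = build_paradigm(seed=config.seed)
            subjects = generate_cohort(spec, design=design, network=net)
            if config.write_inputs:
                write_cohort(subjects, out / "cohort", design)
            cov = covariate_table(subjects)
            bundles = [(s.timeseries, design, s.press_log) for s in subjects]
        else:
            root = Path(config.input_dir)
            cov = pd.read_csv(root / "covariates.csv")
            bundles = []
            for sid in cov.subject:
                ts, design, press, _ = read_subject_bundle(root / sid)
                bundles.append((ts, design, press))
        manifest["stages"][stage] = {"n_subjects": len(bundles)}
        manifest["input_hash"] = _hash(cov.to_csv(index=False))

        # --- behavioral screening -------------------------------------
        behavior_rows = []
        behavior_ok = []
        for sid, (ts, design, press) in zip(cov.subject, bundles):
            if press is None:
                behavior_ok.append(True)
                continue
            scores, summary = score_log(press)
            behavior_ok.append(not summary.excluded)
            for _, r in summary.per_condition.iterrows():
                behavior_rows.append({"subject": sid, **r.to_dict()})
        if behavior_rows:
            pd.DataFrame(behavior_rows).to_csv(out / "behavior.csv", index=False)
        manifest["stages"]["behavior"] = {
            "n_excluded": int(sum(not ok for ok in behavior_ok))
        }

        # --- inversion + QC -------------------------------------------
        stage = "invert"
        priors = default_priors(net)
        posts, diags, fitted_ids = [], [], []
        for sid, (ts, design, press), ok in zip(cov.subject, bundles, behavior_ok):
            if not ok:
                continue
            post, diag = invert(
                ts, design, net, priors,
                dt=config.inversion_dt, max_iter=config.max_iter,
                tol=config.tol, qc_threshold=config.qc_threshold,
            )
            if not config.quiet:
                print(f"[invert] {sid}: iters={post.n_iter} F={post.free_energy:.1f} "
                      f"VE={diag.variance_explained:.2f}")
            posts.append(post)
            diags.append(diag)
            fitted_ids.append(sid)
        if 0 < config.qc_threshold < 1:
            kept, excluded = qc_filter(diags, config.qc_threshold)
        else:  # unreachable threshold: nobody can pass
            kept, excluded = [], list(range(len(diags)))
        manifest["stages"]["invert"] = {
            "n_fitted": len(posts),
            "n_qc_passed": len(kept),
            "n_qc_excluded": len(excluded),
            "mean_variance_explained": float(
                np.mean([d.variance_explained for d in diags])
            ) if diags else float("nan"),
        }
        if not kept:
            manifest["stages"]["aborted"] = (
                "no subject passed QC; downstream stages skipped"
            )
            _write_manifest(manifest, out)
            return manifest

        keep_ids = [fitted_ids[i] for i in kept]
        keep_posts = [posts[i] for i in kept]

        # --- optional group-level post-hoc reduction -------------------
        if config.run_reduction:
            stage = "reduce"
            winner, scored = pooled_posthoc_search(keep_posts, priors)
            labels = np.array(priors.packing.labels)
            manifest["stages"]["reduce"] = {
                "n_pruned": int(winner.n_off),
                "pruned": labels[winner.off_mask].tolist(),
            }
            pd.DataFrame(
                {
                    "off_mask": ["".join("1" if o else "0" for o in m.off_mask)
                                 for m in scored],
                    "delta_F": [m.delta_F for m in scored],
                    "posterior_prob": [m.posterior_prob for m in scored],
                }
            ).to_csv(out / "reduction.csv", index=False)

        # --- parameter table ------------------------------------------
        stage = "stats"
        labels = priors.packing.labels
        conn_cols = [
            lbl for lbl in labels if lbl.startswith(("A:", "B:"))
        ]
        rows = []
        for sid, post in zip(keep_ids, keep_posts):
            row = {"subject": sid}
            row.update({lbl: float(v) for lbl, v in zip(labels, post.mean)})
            rows.append(row)
        ptab = pd.DataFrame(rows).merge(cov, on="subject")
        ptab.to_csv(out / "parameters.csv", index=False)

        results = ancova_per_connection(
            ptab, conn_cols, covariates=config.covariates,
            alpha=config.alpha, n_tests=config.n_tests,
        )
        results_frame(results).to_csv(out / "ancova.csv", index=False)
        sig = [r for r in results if r.significant_bonferroni]
        posthoc_rows = []
        for r in sig:
            for pr in pairwise_posthoc(ptab, r.connection, covariates=config.covariates):
                posthoc_rows.append({"connection": r.connection, **asdict(pr)})
        if posthoc_rows:
            pd.DataFrame(posthoc_rows).to_csv(out / "posthoc.csv", index=False)
        manifest["stages"]["stats"] = {
            "n_connections": len(results),
            "n_significant": len(sig),
            "significant": [r.connection for r in sig],
        }

        # --- clustering over gene carriers ----------------------------
        stage = "cluster"
        carriers = ptab[ptab.group.isin(["preHD", "earlyHD"])]
        manifest["stages"]["cluster"] = {"n_carriers": len(carriers)}
        if len(carriers) > config.k_max + 1:
            X = carriers[conn_cols].to_numpy(float)
            members, sel, schedule = cluster_parameters(
                X, k_max=config.k_max, zscore=config.zscore
            )
            schedule.to_frame().to_csv(out / "agglomeration.csv", index=False)
            memb = carriers[["subject", "group"]].copy()
            memb["cluster"] = members
            memb.to_csv(out / "clusters.csv", index=False)
            manifest["stages"]["cluster"].update(
                {
                    "k": int(sel.k),
                    "confident": bool(sel.confident),
                    "sizes": np.bincount(members)[1:].tolist(),
                }
            )

            # --- covariate-adjusted correlations ----------------------
            stage = "correlate"
            corr_rows = []
            Z = _covariate_matrix(carriers, config.covariates)
            for conn in KEY_CONNECTIONS:
                if conn not in carriers.columns or carriers.putamen.isna().all():
                    continue
                r, p, n = partial_correlation(
                    carriers[conn].to_numpy(float),
                    carriers["putamen"].to_numpy(float),
                    Z,
                )
                corr_rows.append({"pair": f"{conn} vs putamen", "r": r, "p": p, "n": n})
            if corr_rows:
                pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)
                manifest["stages"]["correlate"] = {"n_pairs": len(corr_rows)}
    except Exception as err:  # noqa: BLE001 - abort contract names the stage
        manifest["stages"]["aborted"] = f"stage '{stage}' failed: {err}"
        _write_manifest(manifest, out)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    _write_manifest(manifest, out)
    return manifest


def _covariate_matrix(table: pd.DataFrame, covariates) -> np.ndarray:
    cols = []
    for cov in covariates:
        if table[cov].dtype == object:
            levels = sorted(table[cov].astype(str).unique())
            for lv in levels[1:]:
                cols.append((table[cov].astype(str) == lv).to_numpy(float))
        else:
            cols.append(table[cov].to_numpy(float))
    return np.column_stack(cols) if cols else np.empty((len(table), 0))


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
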