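"""End-to-end analysis: connectomes + EEG + clinical table -> report.

Given a study directory with

    cohort.csv            id, age, sex, hdrs_pre, hdrs_post
    connectomes/<id>.tsv  square connectivity matrix per subject
    eeg/<id>.csv + .json  seizure trace per subject (optional per subject;
                          with several sessions only the first sorted file
                          is used)

this module computes whole-brain controllability and edge count per subject,
PSI per EEG trace, joins everything into one table, and runs the inferential
chain: five directional ANCOVAs (MC-bar/AC-bar -> PSI, PSI -> response,
MC-bar/AC-bar -> response), two PSI-mediation analyses, and optionally the
ML benchmark. Analyses involving PSI use exactly the PSI-available subset;
the others use all subjects. The JSON report carries a provenance block
(seed, config hash, version, per-analysis N, exclusions) and reruns are
byte-identical under a fixed seed and config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .benchmark import (
    connectome_feature_matrix,
    covariate_baseline,
    run_benchmark,
)
from .connectome import edge_count, read_connectome
from .controllability import controllability_profile, stabilize
from .psi import compute_psi, read_eeg
from .stats import HYPOTHESIS_DIRECTIONS, ancova, mediate

__all__ = ["AnalysisReport", "run_full_analysis", "load_config"]

log = logging.getLogger("ectnct")

DEFAULT_COVARIATES = ["age", "sex", "hdrs_pre", "edge_count"]

_ANCOVA_CONTRASTS = [
    ("mc_mean", "psi"),
    ("ac_mean", "psi"),
    ("psi", "response"),
    ("mc_mean", "response"),
    ("ac_mean", "response"),
]


@dataclass(frozen=True)
class AnalysisReport:
    """Full study report: ANCOVAs, mediations, benchmark, provenance."""

    table: pd.DataFrame
    ancova: dict[str, dict]
    mediation: dict[str, dict]
    benchmark: dict | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "ancova": self.ancova,
            "mediation": self.mediation,
            "benchmark": self.benchmark,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def to_text(self) -> str:
        lines = [f"ectnct analysis report (v{self.provenance['version']})", ""]
        for name, res in self.ancova.items():
            lines.append(
                f"ANCOVA {name}: F(1,{res['df2']}) = {res['F']:.2f}, "
                f"one-sided P = {res['p_one_sided']:.3f}, "
                f"eta_p^2 = {res['eta_p_sq']:.3f}  (N = {res['n_used']})"
            )
        lines.append("")
        for name, res in self.mediation.items():
            lines.append(
                f"Mediation {name}: ab = {res['ab']:.3f} "
                f"[{res['ab_ci'][0]:.3f}, {res['ab_ci'][1]:.3f}], "
                f"perm P = {res['p_ab_perm']:.3f}, c' = {res['c_prime']:.3f} "
                f"(N = {res['n_used']})"
            )
        if self.benchmark is not None:
            lines.append("")
            lines.append("ML benchmark (percent variance explained):")
            for k, v in self.benchmark["single_feature"].items():
                lines.append(f"  {k} (single-feature linear): {v:.2f}%")
            for k, v in self.benchmark["best_per_modality"].items():
                lines.append(f"  best pipeline on {k}: {v:.2f}%")
            if "covariate_baseline" in self.benchmark:
                lines.append(
                    f"  covariate baseline: {self.benchmark['covariate_baseline']:.2f}%"
                )
        return "\n".join(lines) + "\n"


def load_config(config: str | Path | dict) -> dict:
    """Load a TOML config file, or pass a dict through."""
    if isinstance(config, dict):
        return config
    with open(config, "rb") as fh:
        return tomllib.load(fh)


def _config_hash(cfg: dict) -> str:
    # hash only the result-affecting sections; where outputs land is not
    # part of the analysis identity
    relevant = {k: v for k, v in cfg.items() if k != "output"}
    canon = json.dumps(relevant, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _first_session_eeg(eeg_dir: Path, sid: str) -> Path | None:
    candidates = sorted(eeg_dir.glob(f"{sid}*.csv"))
    return candidates[0] if candidates else None


def run_full_analysis(config: str | Path | dict) -> AnalysisReport:
    """Run the complete study analysis described by ``config``.

    Config keys (TOML sections flattened as dicts)::

        inputs.dir        study directory (cohort.csv, connectomes/, eeg/)
        analysis.covariates   default ["age", "sex", "hdrs_pre", "edge_count"]
        analysis.n_boot / n_perm / seed
        analysis.benchmark    bool, run the 35-pipeline grid (default off)
        output.dir        where to write report.json / report.txt (optional)
    """
    cfg = load_config(config)
    inputs = cfg.get("inputs", {})
    analysis = cfg.get("analysis", {})
    output = cfg.get("output", {})
    study_dir = Path(inputs["dir"])
    covariates = list(analysis.get("covariates", DEFAULT_COVARIATES))
    n_boot = int(analysis.get("n_boot", 1000))
    n_perm = int(analysis.get("n_perm", 1000))
    seed = int(analysis.get("seed", 0))
    do_benchmark = bool(analysis.get("benchmark", False))

    cohort = pd.read_csv(study_dir / "cohort.csv")
    required = {"id", "age", "sex", "hdrs_pre", "hdrs_post"}
    missing_cols = required - set(cohort.columns)
    if missing_cols:
        raise ValueError(f"cohort.csv missing columns: {sorted(missing_cols)}")
    # derived quantities are always recomputed from the raw inputs; drop any
    # precomputed versions the table may carry so they cannot shadow ours
    cohort = cohort.drop(
        columns=["psi", "ac_mean", "mc_mean", "edge_count", "response"],
        errors="ignore",
    )

    conn_dir = study_dir / "connectomes"
    eeg_dir = study_dir / "eeg"
    rows, excluded, matrices = [], [], {}
    for sid in cohort["id"].astype(str):
        conn_path = None
        for suffix in (".tsv", ".csv", ".txt"):
            p = conn_dir / f"{sid}{suffix}"
            if p.exists():
                conn_path = p
                break
        if conn_path is None:
            excluded.append({"id": sid, "reason": "missing connectome"})
            continue
        try:
            c = read_connectome(conn_path)
            prof = controllability_profile(stabilize(c))
        except ValueError as exc:
            excluded.append({"id": sid, "reason": f"connectome QC failed: {exc}"})
            continue
        matrices[sid] = c.weights
        psi_val = np.nan
        eeg_path = _first_session_eeg(eeg_dir, sid) if eeg_dir.exists() else None
        if eeg_path is not None:
            psi_val = compute_psi(read_eeg(eeg_path)).psi
        rows.append(
            {
                "id": sid,
                "ac_mean": prof.ac_mean,
                "mc_mean": prof.mc_mean,
                "edge_count": edge_count(c),
                "psi": psi_val,
            }
        )
    if excluded:
        for e in excluded:
            log.warning("excluded %(id)s: %(reason)s", e)
    derived = pd.DataFrame(rows)
    table = cohort.astype({"id": str}).merge(derived, on="id", how="inner")
    table["response"] = table["hdrs_post"] - table["hdrs_pre"]

    ancova_results: dict[str, dict] = {}
    for predictor, dependent in _ANCOVA_CONTRASTS:
        sign = HYPOTHESIS_DIRECTIONS[(predictor, dependent)]
        res = ancova(table, dependent, predictor, covariates, sign)
        ancova_results[f"{predictor}->{dependent}"] = dataclasses.asdict(res)

    mediation_results: dict[str, dict] = {}
    for i, predictor in enumerate(("mc_mean", "ac_mean")):
        res = mediate(
            table,
            predictor=predictor,
            mediator="psi",
            outcome="response",
            covariates=covariates,
            n_boot=n_boot,
            n_perm=n_perm,
            seed=seed + i,
        )
        d = dataclasses.asdict(res)
        d["ab_ci"] = list(d["ab_ci"])
        mediation_results[f"{predictor}->psi->response"] = d

    benchmark_block = None
    if do_benchmark:
        complete = table.dropna(subset=["response", "ac_mean", "mc_mean"])
        X = connectome_feature_matrix([matrices[s] for s in complete["id"]])
        bench = run_benchmark(
            {"streamlines": X},
            complete[["ac_mean", "mc_mean"]],
            complete["response"].to_numpy(),
            seed=seed,
        )
        benchmark_block = {
            "results": bench.results.to_dict(orient="records"),
            "best_per_modality": bench.best_per_modality,
            "single_feature": bench.single_feature,
            "covariate_baseline": covariate_baseline(complete),
        }

    provenance = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(cfg),
        "covariates": covariates,
        "direction_map": {
            f"{p}->{d}": s for (p, d), s in HYPOTHESIS_DIRECTIONS.items()
        },
        "n_subjects_input": int(len(cohort)),
        "n_subjects_analyzed": int(len(table)),
        "n_per_analysis": {
            name: res["n_used"]
            for name, res in {**ancova_results, **mediation_results}.items()
        },
        "exclusions": excluded,
        "n_boot": n_boot,
        "n_perm": n_perm,
    }

    report = AnalysisReport(
        table=table,
        ancova=ancova_results,
        mediation=mediation_results,
        benchmark=benchmark_block,
        provenance=provenance,
    )
    out_dir = output.get("dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        (out / "report.txt").write_text(report.to_text())
        table.to_csv(out / "analysis_table.csv", index=False)
    return report
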