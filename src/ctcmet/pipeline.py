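"""End-to-end pipeline orchestration with a validated configuration.

``run_pipeline`` executes the enabled stages in order — simulate,
screen, subtype, classify — writing every intermediate table plus a
provenance block (config hash, seed, package version) so a run can be
replayed exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as ctcio
from .patient_risk import (
    aggregate_patient_counts,
    optimal_count_cutoff,
    performance_metrics,
    roc_auc,
)
from .screening import (
    differential_table,
    filter_features,
    impute_missing,
    normalize_bulk,
    opls_da,
    shared_panel,
)
from .subtyping import (
    FINGERPRINT,
    assign_subgroups,
    consensus_cluster,
    fit_risk_model,
    published_risk_model,
    risk_score,
)
from .synthetic import CohortSimConfig, ScreenSimConfig, generate_bulk_screen, generate_ctc_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("ctcmet")


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline stages and thresholds; defaults are the published constants."""

    seed: int = 0
    out_dir: str = "ctcmet_out"
    simulate: bool = True
    screen: bool = True
    subtype: bool = True
    classify: bool = True
    use_published_model: bool = False
    # screening thresholds
    min_detect_frac: float = 0.8
    min_snr: float = 3.0
    # subtyping
    risk_threshold: float = 0.420
    n_consensus_runs: int = 30
    k_min: int = 2
    k_max: int = 6
    # patient classification (published count cutoffs)
    total_cutoff: int = 3
    c1_cutoff: int = 1
    c2_cutoff: int = 1
    # simulation sizes
    n_patients: int = 60
    n_features: int = 300
    log_level: str = "info"

    def __post_init__(self) -> None:
        if not 0 < self.risk_threshold < 1:
            raise ValueError(
                f"risk_threshold must be in (0,1), got {self.risk_threshold}"
            )
        if not 0 < self.min_detect_frac <= 1:
            raise ValueError("min_detect_frac must be in (0,1]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")
        for name in ("total_cutoff", "c1_cutoff", "c2_cutoff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.log_level not in ("debug", "info", "warn"):
            raise ValueError(f"unknown log_level {self.log_level!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns the report bundle (also written out)."""
    logging.basicConfig(
        level={"debug": logging.DEBUG, "info": logging.INFO, "warn": logging.WARNING}[
            config.log_level
        ],
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_digest": config.digest(),
            "config": config.to_dict(),
        }
    }

    if config.screen:
        logger.info("screening stage: simulating and screening bulk matrices")
        scfg = ScreenSimConfig(n_features=config.n_features, seed=config.seed)
        (pair_a, pair_b), truth = generate_bulk_screen(scfg)
        tables = []
        for name, fm in (("pairA", pair_a), ("pairB", pair_b)):
            blank = pd.Series(1.0, index=fm.feature_ids)
            fm = filter_features(
                fm, config.min_detect_frac, config.min_snr, blank_profile=blank
            )
            fm = normalize_bulk(impute_missing(fm))
            model = opls_da(fm)
            tab = differential_table(fm, ("primary", "metastatic"), model)
            tab.to_csv(out / f"differential_{name}.tsv", sep="\t", index=False)
            tables.append(tab)
        panel = shared_panel(*tables)
        (out / "shared_panel.json").write_text(json.dumps(panel, indent=2))
        report["screen"] = {
            "selected_pairA": int(tables[0]["selected"].sum()),
            "selected_pairB": int(tables[1]["selected"].sum()),
            "shared_panel_size": len(panel),
            "planted_differential": len(truth.differential_feature_ids),
        }

    cells = patients = None
    if config.simulate:
        logger.info("simulating CTC cohort (%d patients)", config.n_patients)
        ccfg = CohortSimConfig(n_patients=config.n_patients, seed=config.seed)
        cells, patients, truth_c = generate_ctc_cohort(ccfg)
        ctcio.write_single_cell_matrix(
            cells, out / "cells.csv", out / "cell_annotations.csv"
        )
        ctcio.write_patient_table(patients, out / "patients_true.csv")

    if config.subtype:
        if cells is None:
            raise ValueError("subtype stage requires simulated or loaded cells")
        if config.use_published_model:
            model = published_risk_model()
        else:
            logger.info("consensus NMF rank selection")
            cons = consensus_cluster(
                cells,
                k_range=range(config.k_min, config.k_max + 1),
                n_runs=config.n_consensus_runs,
                seed=config.seed,
            )
            report["subtype"] = {
                "selected_rank": cons.selected_rank,
                "cophenetic": {str(k): v for k, v in cons.cophenetic.items()},
            }
            model = fit_risk_model(
                cells,
                cons.cell_labels,
                fingerprint=FINGERPRINT,
                outcomes=patients["outcome"] if patients is not None else None,
            )
        ctcio.write_risk_model(model, out / "risk_model.json")
        scores = risk_score(model, cells.concentrations)
        labels = assign_subgroups(scores, model.threshold)
        pd.DataFrame(
            {"risk_score": scores, "subgroup": labels}, index=cells.cell_ids
        ).to_csv(out / "cell_subgroups.csv")
        report.setdefault("subtype", {})["c2_fraction"] = float(
            np.mean(labels == "C2")
        )

        if config.classify:
            counts = aggregate_patient_counts(cells.patient_ids, labels)
            table = counts.join(patients[["outcome"]], how="left")
            ctcio.write_patient_table(table, out / "patient_counts.csv")
            y = table["outcome"].to_numpy()
            metrics = {}
            for stat, col, direction, cutoff in (
                ("total_ctc", "total_ctc_count", "greater", config.total_cutoff),
                ("c1", "c1_count", "less", config.c1_cutoff),
                ("c2", "c2_count", "greater", config.c2_cutoff),
            ):
                vals = table[col].to_numpy()
                roc = roc_auc(vals, y, direction)
                opt = optimal_count_cutoff(vals, y, direction)
                pred = vals > cutoff if direction == "greater" else vals < cutoff
                pm = performance_metrics(
                    pred, y, auc=roc.auc, cutoff=cutoff, direction=direction
                )
                metrics[stat] = {
                    "auc": roc.auc,
                    "optimal_cutoff": opt,
                    "cutoff_used": cutoff,
                    "confusion": {"tp": pm.tp, "fp": pm.fp, "tn": pm.tn, "fn": pm.fn},
                    **pm.as_percent(),
                }
            report["classify"] = metrics
            (out / "metrics.json").write_text(
                json.dumps(metrics, indent=2, sort_keys=True, default=_json_default)
            )

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default)
    )
    logger.info("pipeline finished; outputs in %s", out)
    return report
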