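"""Clinical-table IO, split assignment, run configuration, and the pipeline.

The clinical CSV schema has required columns
``id, age, sex, histology, lobe, stage, os_time, os_event, rfs_time,
rfs_event`` and an optional ``split`` column; when ``split`` is missing it
is generated by a seeded 75/12.5/12.5 assignment (test and validation sizes
round down, training takes the remainder, so a 1705-patient table splits
1279/213/213).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .evaluation import compare_models, concordance, evaluate_model
from .model import TrainConfig, save_model, train
from .records import PatientRecord, RecordValidationError, STAGE_ORDINAL
from .similarity import SimilarityConfig, build_graph, write_graph
from .synthetic import CohortSpec, generate_cohort

logger = logging.getLogger("graphsurv")

CLINICAL_COLUMNS = ["id", "age", "sex", "histology", "lobe", "stage",
                    "os_time", "os_event", "rfs_time", "rfs_event"]


class ClinicalTableError(ValueError):
    """One or more rows of a clinical table violate the schema."""


def read_clinical(path) -> List[PatientRecord]:
    """Read and validate a clinical CSV; errors cite the offending rows."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ClinicalTableError(f"{path}: missing required columns {missing}")
    errors: List[str] = []
    records: List[PatientRecord] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2  # header occupies line 1
        try:
            rec = PatientRecord(
                id=str(row.id), age=float(row.age), sex=str(row.sex),
                histology=str(row.histology), lobe=str(row.lobe), stage=str(row.stage),
                os_time=float(row.os_time), os_event=int(row.os_event),
                rfs_time=float(row.rfs_time), rfs_event=int(row.rfs_event),
                split=(str(row.split) if "split" in df.columns
                       and pd.notna(getattr(row, "split", None)) else None),
            )
            errs = rec.validate()
        except (TypeError, ValueError) as exc:
            errs = [str(exc)]
            rec = None
        if errs:
            errors.append(f"line {line_no}: " + "; ".join(errs))
        else:
            records.append(rec)
    if errors:
        raise ClinicalTableError(f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ClinicalTableError(f"{path}: duplicated patient ids")
    return records


def write_clinical(records: Sequence[PatientRecord], path) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows)
    cols = CLINICAL_COLUMNS + (["split"] if any(r.split for r in records) else [])
    df[cols].to_csv(path, index=False)


def read_features(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def write_features(features: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(features, dtype=float), delimiter="\t")


def assign_splits(records: Sequence[PatientRecord],
                  fractions: Tuple[float, float, float] = (0.75, 0.125, 0.125),
                  seed: int = 0) -> List[PatientRecord]:
    """Seeded random train/val/test assignment.

    Test and validation sizes are floor(n * fraction); training receives
    the remainder (1705 -> 1279/213/213).
    """
    n = len(records)
    if n < 3:
        raise ClinicalTableError(f"need at least 3 records to split, got {n}")
    f_train, f_val, f_test = fractions
    if abs(f_train + f_val + f_test - 1.0) > 1e-9 or min(fractions) < 0:
        raise ClinicalTableError(f"fractions must be non-negative and sum to 1, got {fractions}")
    n_test = int(n * f_test)
    n_val = int(n * f_val)
    perm = np.random.default_rng(seed).permutation(n)
    split = np.empty(n, dtype=object)
    split[perm[:n_test]] = "test"
    split[perm[n_test:n_test + n_val]] = "val"
    split[perm[n_test + n_val:]] = "train"
    return [r.with_split(s) for r, s in zip(records, split)]


# --------------------------------------------------------------------------
# Run configuration

@dataclass
class RunConfig:
    """Everything needed for one end-to-end run; JSON round-trippable."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    split_fractions: Tuple[float, float, float] = (0.75, 0.125, 0.125)
    horizon: float = 60.0
    n_boot: int = 1000
    seed: int = 0
    clinical_path: Optional[str] = None   # load instead of simulating
    features_path: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        raw["cohort"] = CohortSpec(**{k: tuple(v) if isinstance(v, list) else v
                                      for k, v in raw["cohort"].items()})
        raw["similarity"] = SimilarityConfig(**raw["similarity"])
        raw["training"] = TrainConfig(**raw["training"])
        raw["split_fractions"] = tuple(raw["split_fractions"])
        return cls(**raw)


def stage_baseline_risks(records: Sequence[PatientRecord]) -> np.ndarray:
    """TNM-style baseline: the pTNM sub-stage ordinal as the risk score."""
    return np.array([STAGE_ORDINAL[r.stage] for r in records], dtype=float)


# --------------------------------------------------------------------------
# Pipeline

def run_pipeline(config: RunConfig, out_dir) -> Dict[str, object]:
    """simulate/load -> graph -> train -> evaluate; artifacts written to out_dir.

    Returns a dict with the graph, train result, reports, and artifact
    paths.  A structured JSON-lines log records per-stage timings and the
    seeds in effect.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_fh = open(log_path, "w")

    def stage(name: str, **extra):
        entry = {"stage": name, "time": time.time(), **extra}
        log_fh.write(json.dumps(entry) + "\n")
        log_fh.flush()
        logger.info("stage %s %s", name, extra)

    try:
        if config.clinical_path:
            stage("load", clinical=config.clinical_path, features=config.features_path)
            records = read_clinical(config.clinical_path)
            features = read_features(config.features_path)
        else:
            stage("simulate", seed=config.cohort.seed, n=config.cohort.n_patients)
            cohort = generate_cohort(config.cohort)
            records, features = cohort.records, cohort.features
        if any(r.split is None for r in records):
            stage("assign_splits", seed=config.seed, fractions=config.split_fractions)
            records = assign_splits(records, config.split_fractions, config.seed)
        write_clinical(records, out / "clinical.csv")
        write_features(features, out / "features.tsv")

        t0 = time.time()
        graph = build_graph(records, features, config.similarity)
        stage("build_graph", n_nodes=graph.n_nodes, n_edges=graph.n_edges,
              elapsed=time.time() - t0)
        write_graph(graph, out / "graph_edges.tsv")

        t0 = time.time()
        result = train(graph, config.training)
        stage("train", seed=config.training.seed, epochs_run=len(result.log),
              best_epoch=result.best_epoch, elapsed=time.time() - t0)
        save_model(result.model, str(out / "model"))
        pd.DataFrame(result.log, columns=["epoch", "train_loss", "val_loss"]).to_csv(
            out / "training_log.csv", index=False)

        ordered = graph.records
        risks_df = pd.DataFrame({
            "id": graph.node_ids,
            "risk": result.risks,
            "split": [r.split for r in ordered],
        })
        risks_df.to_csv(out / "risks.csv", index=False)

        t0 = time.time()
        model_risks = {
            "graph_model": result.risks,
            "stage_baseline": stage_baseline_risks(ordered),
        }
        endpoints = {"OS": (graph.os_time, graph.os_event),
                     "RFS": (graph.rfs_time, graph.rfs_event)}
        reports = compare_models(
            model_risks, endpoints, graph.masks["train"],
            baseline="stage_baseline", eval_mask=graph.masks["test"],
            horizon=config.horizon, n_boot=config.n_boot, seed=config.seed,
        )
        stage("evaluate", elapsed=time.time() - t0, seed=config.seed)

        report_dict = {m: {ep: rep.to_dict() for ep, rep in by_ep.items()}
                       for m, by_ep in reports.items()}
        test = graph.masks["test"]
        report_dict["test_concordance"] = {
            ep: concordance(t[test], model_risks["graph_model"][test], e[test])
            for ep, (t, e) in endpoints.items()
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report_dict, fh, indent=2)

        try:
            _write_plots(graph, result.risks, reports, out)
            stage("plots")
        except Exception as exc:  # plotting must never sink a run
            stage("plots_failed", error=str(exc))

        stage("done")
        return {"graph": graph, "result": result, "reports": reports,
                "out_dir": str(out)}
    except Exception as exc:
        stage("error", error=str(exc))
        raise
    finally:
        log_fh.close()


def _write_plots(graph, risks, reports, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .evaluation import km_curve, risk_stratify

    groups = risk_stratify(risks, graph.masks["train"])
    test = graph.masks["test"]
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, ep in zip(axes, ("OS", "RFS")):
        t, e = graph.survival(ep)
        for cls, color in (("low", "tab:blue"), ("high", "tab:red")):
            sel = test & (groups.labels == cls)
            if sel.sum() and e[sel].sum():
                curve = km_curve(t[sel], e[sel])
                ax.step(curve.event_times, curve.survival, where="post",
                        label=f"{cls} risk", color=color)
        ax.set_title(f"{ep} (test set)")
        ax.set_xlabel("months")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
        ax.legend()
    fig.tight_layout()
    fig.savefig(out / "km_curves.png", dpi=100)
    plt.close(fig)

    rep = reports["graph_model"]["OS"]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(rep.dca_thresholds, rep.dca_net_benefit, label="graph model")
    ax.plot(rep.dca_thresholds, rep.dca_net_benefit_all, "--", label="treat all")
    ax.axhline(0.0, color="k", lw=0.8, label="treat none")
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.set_ylim(bottom=-0.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "dca_os.png", dpi=100)
    plt.close(fig)
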