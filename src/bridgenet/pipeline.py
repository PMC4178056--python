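"""End-to-end pipeline orchestration driven by a declarative run config."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bridgeness import rank_bridges
from .discriminate import (
    cumulative_classification_cv,
    per_gene_t_tests,
    random_feature_baseline,
    zscore_normalize,
)
from .io_formats import (
    InteractionKind,
    read_expression_matrix,
    read_gene_list,
    read_interaction_table,
    read_survival_table,
    write_network,
)
from .network import (
    TissuePanel,
    assign_edge_distances,
    extract_reference_network,
    filter_by_tissue_expression,
    integrate_interactions,
)
from .prognosis import SurvivalCohort, classify_by_correlation, evaluate_prognosis, train_prognostic_model

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


_REQUIRED = ("ppi", "pdi", "sensors", "enzymes", "out_dir")


@dataclass
class RunConfig:
    """Declarative description of a full pipeline run.

    File paths for interactions, gene sets, expression and survival tables;
    the tissue-filter percentile; the marker count k; CV parameters; and the
    seed driving every stochastic stage.
    """

    ppi: str
    pdi: str
    sensors: str
    enzymes: str
    out_dir: str
    coexpression: str | None = None
    tissue_panel: str | None = None
    tissue_target_samples: list[str] = field(default_factory=list)
    percentile_cutoff: float = 40.0
    expression: str | None = None
    labels: dict[str, str] = field(default_factory=dict)
    class_a: str = "normal"
    class_b: str = "tumor"
    survival_train: str | None = None
    survival_test: str | None = None
    expression_test: str | None = None
    top_k: int = 50
    folds: int = 5
    cv_repeats: int = 5
    threshold_repeats: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = [k for k in _REQUIRED if k not in payload]
        if missing:
            raise ConfigError(f"missing required config keys: {missing}")
        return cls(**payload)

    def validate(self) -> None:
        for key in ("ppi", "pdi", "sensors", "enzymes", "coexpression", "tissue_panel",
                    "expression", "survival_train", "survival_test", "expression_test"):
            value = getattr(self, key)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"config path for {key!r} does not exist: {value}")

    def digest(self) -> str:
        canon = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute construction -> scoring -> optional discrimination/prognosis.

    Writes the reference network, the bridgeness table, accuracy curves and
    the prognostic model into ``out_dir`` together with a provenance manifest
    (all parameters, package version, seed, config hash).  Any stage error
    aborts with the stage name; partial outputs stay on disk next to a
    ``FAILED`` marker naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.digest(),
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: getattr(config, k) for k in sorted(config.__dataclass_fields__)},
        "stages": [],
    }
    stage = "construction"
    try:
        ppi = read_interaction_table(config.ppi, InteractionKind.PPI)
        pdi = read_interaction_table(config.pdi, InteractionKind.PDI)
        sensors = read_gene_list(config.sensors)
        enzymes = read_gene_list(config.enzymes)
        net = integrate_interactions(ppi, pdi)
        if config.coexpression:
            net = assign_edge_distances(net, read_expression_matrix(config.coexpression))
        net.set_roles(sensors, enzymes)
        if config.tissue_panel:
            panel_expr = read_expression_matrix(config.tissue_panel)
            panel = TissuePanel(panel_expr.values, list(config.tissue_target_samples))
            net = filter_by_tissue_expression(net, panel, config.percentile_cutoff)
        net = extract_reference_network(net, sensors, enzymes)
        write_network(net, out / "reference_network.tsv", "edge_tsv")
        manifest["stages"].append(stage)
        manifest["network"] = {
            "n_nodes": net.graph.number_of_nodes(),
            "n_edges": net.graph.number_of_edges(),
        }

        stage = "scoring"
        table = rank_bridges(net, sorted(net.sensors), sorted(net.enzymes))
        table.to_tsv(out / "bridgeness.tsv")
        top_genes = table.top(config.top_k)
        manifest["stages"].append(stage)
        manifest["top_bridges"] = top_genes[: min(10, len(top_genes))]

        if config.expression:
            stage = "discrimination"
            expr = zscore_normalize(
                read_expression_matrix(config.expression, class_map=config.labels)
            )
            a = expr.samples_of_class(config.class_a)
            b = expr.samples_of_class(config.class_b)
            tests = per_gene_t_tests(expr, a, b)
            tests.table.to_csv(out / "t_tests.tsv", sep="\t", index=False, float_format="%.6g")
            two_class = [s for s in expr.samples if s in set(a) | set(b)]
            sub = expr.values[two_class]
            labels = expr.sample_class.loc[two_class]
            from .io_formats import ExpressionMatrix

            sub_expr = ExpressionMatrix(sub, labels)
            usable = [g for g in top_genes if g in sub.index]
            grid = [k for k in range(2, len(usable) + 1)] or None
            if usable and grid:
                curve = cumulative_classification_cv(
                    sub_expr, usable, labels, grid=grid, folds=config.folds,
                    repeats=config.cv_repeats, seed=config.seed,
                )
                baseline = random_feature_baseline(
                    sub_expr, labels, grid=grid, repeats=20, folds=config.folds,
                    seed=config.seed,
                )
                curves = pd.concat(
                    [curve.table.assign(source="bridge"), baseline.table.assign(source="random")]
                )
                curves.to_csv(out / "accuracy_curves.tsv", sep="\t", index=False,
                              float_format="%.6f")
            manifest["stages"].append(stage)

        if config.survival_train and config.expression:
            stage = "prognosis"
            surv = read_survival_table(config.survival_train)
            expr = zscore_normalize(read_expression_matrix(config.expression))
            shared = [s for s in expr.samples if s in surv.index]
            cohort = SurvivalCohort(surv.loc[shared], expr.values[shared])
            markers = [g for g in top_genes if g in expr.values.index]
            model = train_prognostic_model(
                cohort, markers, folds=config.folds, repeats=config.threshold_repeats,
                seed=config.seed,
            )
            model.to_yaml(out / "prognostic_model.yaml")
            if config.survival_test and config.expression_test:
                test_surv = read_survival_table(config.survival_test)
                test_expr = zscore_normalize(read_expression_matrix(config.expression_test))
                t_shared = [s for s in test_expr.samples if s in test_surv.index]
                test_cohort = SurvivalCohort(test_surv.loc[t_shared], test_expr.values[t_shared])
                labels = classify_by_correlation(test_cohort, model)
                p, _ = evaluate_prognosis(test_cohort, labels)
                manifest["test_logrank_p"] = p
                labels.to_frame().to_csv(out / "test_classification.tsv", sep="\t")
            manifest["stages"].append(stage)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
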