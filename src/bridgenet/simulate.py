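"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate, structurally, the data the pipeline consumes:

* :func:`simulate_interactome` — a sparse directed interactome in which every
  sensor-to-enzyme route passes through a planted layer of relay ("bridge")
  nodes: sensor->bridge edges are protein-DNA interactions (directional, as
  from a nuclear-receptor transcription factor) and bridge-enzyme edges are
  protein-protein interactions (bidirectional).  Random decoy edges are added
  among the remaining nodes, but never one that would open a bridge-free
  sensor->enzyme path, so top-k bridgeness must recover the planted set.
* :func:`simulate_expression` — Gaussian log-scale expression with planted
  class-differential genes (mean shift in the tumor class) and optional
  equicorrelated gene blocks for co-expression-distance tests.
* :func:`simulate_cohort` — right-censored survival driven by a planted
  signature: poor-prognosis patients carry expression near a fixed template
  on the signature genes and an exponential event hazard multiplied by the
  hazard ratio; censoring is independent exponential, calibrated to a target
  censoring fraction.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, InteractionKind, InteractionRecord
from .prognosis import SurvivalCohort


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator, serialized alongside outputs."""

    bridges: list[str] = field(default_factory=list)
    sensors: list[str] = field(default_factory=list)
    enzymes: list[str] = field(default_factory=list)
    differential_genes: list[str] = field(default_factory=list)
    signature_genes: list[str] = field(default_factory=list)
    hazard_ratio: float | None = None
    poor_samples: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def simulate_interactome(
    n_nodes: int = 38,
    n_sensors: int = 2,
    n_enzymes: int = 3,
    n_bridges: int = 3,
    decoy_edge_prob: float = 0.08,
    seed: int = 0,
) -> tuple[list[InteractionRecord], list[InteractionRecord], SyntheticTruth]:
    """Interactome with an exclusive planted relay layer.

    Returns (ppi records, pdi records, truth).  Sensors connect to every
    bridge by a PDI and every bridge to every enzyme by a PPI, so each
    sensor->enzyme shortest path has length 2 and passes a bridge.  Decoy
    PPIs among {sensors, enzymes, decoys} are sampled at ``decoy_edge_prob``
    and rejected whenever they would open a sensor->enzyme path avoiding all
    bridges (checked by reachability on the bridge-deleted graph).
    """
    if n_bridges < 1:
        raise ValueError("need at least one planted bridge")
    n_decoys = n_nodes - n_sensors - n_enzymes - n_bridges
    if n_decoys < 0:
        raise ValueError("n_nodes too small for the requested sensor/enzyme/bridge counts")
    rng = np.random.default_rng(seed)
    sensors = [f"S{i+1:02d}" for i in range(n_sensors)]
    enzymes = [f"E{i+1:02d}" for i in range(n_enzymes)]
    bridges = [f"B{i+1:02d}" for i in range(n_bridges)]
    decoys = [f"G{i+1:03d}" for i in range(n_decoys)]

    pdi = [
        InteractionRecord(s, b, InteractionKind.PDI) for s in sensors for b in bridges
    ]
    ppi = [
        InteractionRecord(b, e, InteractionKind.PPI) for b in bridges for e in enzymes
    ]

    # decoy PPIs: bidirectional edges among non-bridge nodes, rejected if a
    # bridge-free sensor->enzyme path would appear
    others = sensors + enzymes + decoys
    probe = nx.Graph()  # bridge-free world is undirected (PPIs only)
    probe.add_nodes_from(others)
    candidates = [
        (others[i], others[j])
        for i in range(len(others))
        for j in range(i + 1, len(others))
    ]
    rng.shuffle(candidates)
    for u, v in candidates:
        if rng.random() >= decoy_edge_prob:
            continue
        probe.add_edge(u, v)
        opens_path = any(
            nx.has_path(probe, s, e) for s in sensors for e in enzymes
        )
        if opens_path:
            probe.remove_edge(u, v)
            continue
        ppi.append(InteractionRecord(u, v, InteractionKind.PPI))

    truth = SyntheticTruth(
        bridges=bridges,
        sensors=sensors,
        enzymes=enzymes,
        params={
            "n_nodes": n_nodes, "n_sensors": n_sensors, "n_enzymes": n_enzymes,
            "n_bridges": n_bridges, "decoy_edge_prob": decoy_edge_prob, "seed": seed,
        },
    )
    return ppi, pdi, truth


def simulate_expression(
    genes: list[str] | int = 500,
    n_per_class: dict[str, int] | None = None,
    diff_genes: list[str] | int = 0,
    effect_size: float = 1.5,
    corr_blocks: list[list[str]] | None = None,
    corr_block_rho: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Class-labelled expression with planted differential genes and blocks.

    Background is Gaussian N(0, 1) per gene and sample (log-scale units).
    ``diff_genes`` (a list, or a count taken from the front of the gene
    list) get a mean shift of ``effect_size`` in the ``tumor`` class.  Genes
    in a common ``corr_blocks`` group share a latent factor giving pairwise
    correlation ``corr_block_rho``.  Default class sizes follow a
    normal / polyp / tumor cohort of 54 / 49 / 186 samples.
    """
    if not 0 <= corr_block_rho < 1:
        raise ValueError("corr_block_rho must be in [0, 1)")
    if abs(effect_size) >= 10:
        raise ValueError("effect size out of the supported range")
    rng = np.random.default_rng(seed)
    if isinstance(genes, int):
        genes = [f"G{i+1:04d}" for i in range(genes)]
    if isinstance(diff_genes, int):
        diff_genes = genes[:diff_genes]
    unknown = set(diff_genes) - set(genes)
    if unknown:
        raise ValueError(f"differential genes outside the universe: {sorted(unknown)[:5]}")
    if n_per_class is None:
        n_per_class = {"normal": 54, "polyp": 49, "tumor": 186}
    samples, classes = [], []
    for label, n in n_per_class.items():
        for j in range(n):
            samples.append(f"{label[:1].upper()}{j+1:03d}")
            classes.append(label)
    values = rng.normal(0.0, noise_sd, size=(len(genes), len(samples)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for block in corr_blocks or []:
        rows = [gene_pos[g] for g in block]
        z = rng.normal(0.0, 1.0, size=len(samples))
        eps = rng.normal(0.0, 1.0, size=(len(rows), len(samples)))
        values[rows, :] = np.sqrt(corr_block_rho) * z + np.sqrt(1 - corr_block_rho) * eps
    tumor_cols = [j for j, c in enumerate(classes) if c == "tumor"]
    for g in diff_genes:
        values[gene_pos[g], tumor_cols] += effect_size
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        pd.Series(classes, index=samples),
    )
    truth = SyntheticTruth(
        differential_genes=list(diff_genes),
        params={
            "n_per_class": dict(n_per_class), "effect_size": effect_size,
            "corr_block_rho": corr_block_rho, "seed": seed,
        },
    )
    return expr, truth


def _signature_template(signature_genes: list[str], amplitude: float) -> pd.Series:
    """Fixed +/- template over the signature genes (sign alternates by index),
    so correlation to the template reflects the pattern rather than overall
    expression level."""
    signs = np.where(np.arange(len(signature_genes)) % 2 == 0, 1.0, -1.0)
    return pd.Series(signs * amplitude, index=signature_genes)


def simulate_cohort(
    n_patients: int = 150,
    markers: list[str] | int = 50,
    signature_genes: list[str] | int = 25,
    hazard_ratio: float = 4.0,
    censor_rate: float = 0.2,
    poor_fraction: float = 1 / 3,
    baseline_hazard: float = 0.02,
    template_amplitude: float = 2.0,
    poor_noise_sd: float = 0.6,
    seed: int = 0,
    sample_prefix: str = "P",
) -> tuple[SurvivalCohort, SyntheticTruth]:
    """Survival cohort with a planted poor-prognosis expression signature.

    Each patient is latently poor with probability ``poor_fraction``.  Poor
    patients' signature-gene expression is drawn around a fixed +/- template;
    all other expression is N(0, 1).  Event times are exponential with rate
    ``baseline_hazard`` (per month), multiplied by ``hazard_ratio`` for poor
    patients; independent exponential censoring is calibrated by bisection so
    the expected censored fraction equals ``censor_rate``.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    if not 0 < poor_fraction < 1:
        raise ValueError("poor_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if isinstance(markers, int):
        markers = [f"M{i+1:03d}" for i in range(markers)]
    if isinstance(signature_genes, int):
        signature_genes = markers[:signature_genes]
    if not set(signature_genes) <= set(markers):
        raise ValueError("signature genes must be a subset of the marker genes")
    samples = [f"{sample_prefix}{i+1:04d}" for i in range(n_patients)]
    poor = rng.random(n_patients) < poor_fraction
    values = rng.normal(0.0, 1.0, size=(len(markers), n_patients))
    template = _signature_template(list(signature_genes), template_amplitude)
    sig_rows = [markers.index(g) for g in signature_genes]
    for row, g in zip(sig_rows, signature_genes):
        values[row, poor] = template[g] + rng.normal(0.0, poor_noise_sd, size=int(poor.sum()))
    hazards = np.where(poor, baseline_hazard * hazard_ratio, baseline_hazard)
    event_times = rng.exponential(1.0 / hazards)
    if censor_rate == 0.0:
        times, events = event_times, np.ones(n_patients, dtype=int)
    else:
        mu = _calibrate_censoring(hazards, censor_rate)
        censor_times = rng.exponential(1.0 / mu, size=n_patients)
        events = (event_times <= censor_times).astype(int)
        times = np.minimum(event_times, censor_times)
    cohort = SurvivalCohort(
        survival=pd.DataFrame({"time": times, "event": events}, index=pd.Index(samples, name="sample")),
        expression=pd.DataFrame(values, index=markers, columns=samples),
    )
    truth = SyntheticTruth(
        signature_genes=list(signature_genes),
        hazard_ratio=hazard_ratio,
        poor_samples=[s for s, flag in zip(samples, poor) if flag],
        params={
            "n_patients": n_patients, "censor_rate": censor_rate,
            "poor_fraction": poor_fraction, "baseline_hazard": baseline_hazard,
            "template_amplitude": template_amplitude, "poor_noise_sd": poor_noise_sd,
            "seed": seed,
        },
    )
    return cohort, truth


def _calibrate_censoring(hazards: np.ndarray, censor_rate: float) -> float:
    """Exponential censoring rate mu with mean P(censored) = mu/(lambda+mu)
    across patients equal to ``censor_rate``; solved by bisection."""
    def frac(mu: float) -> float:
        return float(np.mean(mu / (hazards + mu)))

    lo, hi = 1e-12, float(hazards.max())
    while frac(hi) < censor_rate:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < censor_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
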