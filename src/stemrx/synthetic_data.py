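"""Generators that fabricate every input the pipeline consumes.

The study the pipeline serves profiles 140 stemness/ABC-transporter genes on
TaqMan array cards in two culture conditions with two biological replicates
per condition, then matches prioritised genes against drug–gene interaction
and clinical-trial snapshots.  These generators emulate that shape: Ct
cards with planted 3-cycle condition effects and half-cycle technical
noise, a sparse bipartite drug–gene interaction table, a Poisson trial
registry with the vocabulary of public trial registers, and the assorted
licence/evidence/association side tables.

Reproducibility: one root seed feeds ``numpy.random.SeedSequence`` with a
fixed ``spawn_key`` per generator (cards=0, interactions=1, registry=2,
redo=3, associations=4, edges=5), so adding a generator never perturbs the
streams of existing ones.

The "engineered" bundle is a deterministic fixture whose target panel has
21 genes of which exactly 13 are drug-covered (62%), mirroring the coverage
ratio the real screen reports, with a protein-association network in which
one hub touches 10 partners and a 5-gene mutually-interacting core exists.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ct_model import (
    MAX_CYCLES,
    ArrayCard,
    Condition,
    CtMeasurement,
    Platform,
)

_PHASE_VOCAB = ["Other", "Phase 1", "Phase 1/2", "Phase 2", "Phase 2/3", "Phase 3", "Phase 4"]
_PHASE_WEIGHTS = [0.15, 0.22, 0.08, 0.33, 0.02, 0.12, 0.08]
_STATUS_VOCAB = [
    "Recruiting",
    "Active, not recruiting",
    "Completed",
    "Ongoing",
    "Not yet recruiting",
    "Other",
]
_STATUS_WEIGHTS = [0.35, 0.15, 0.2, 0.1, 0.15, 0.05]
_CANCER_VOCAB = [
    "GI",
    "Breast",
    "CNS",
    "Lung",
    "Urological",
    "Leukaemia",
    "Lymphoma",
    "Multiple cancer types",
    "Bone Sarcoma",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design.

    140-gene panel, two replicates per culture condition, planted condition
    effects of −3 cycles (a 3-cycle Ct drop ≈ 8-fold RNA increase in 3D)
    and 0.5-cycle Gaussian technical noise.
    """

    seed: int = 0
    n_genes: int = 140
    n_samples_per_group: int = 2
    effect_genes: dict[str, float] = field(
        default_factory=lambda: {"ABCG1": -3.0, "POU5F1": -3.0}
    )
    noise_sd: float = 0.5
    baseline_ct_range: tuple[float, float] = (22.0, 34.0)
    n_drugs: int = 60
    n_gene_targets: int = 21
    edge_density: float = 0.1
    trial_rate: float = 3.0
    oncology_trial_fraction: float = 0.35

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0.0 <= self.edge_density <= 1.0):
            raise ValueError("edge_density must lie in [0, 1]")
        if self.trial_rate < 0:
            raise ValueError("trial_rate must be nonnegative")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named stream (fixed spawn key)."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


def packaged_target_panel() -> list[str]:
    """The packaged synthetic 21-gene stemness/chemoresistance panel."""
    text = (
        importlib.resources.files("stemrx.data")
        .joinpath("es_csc_targets_synthetic.txt")
        .read_text()
    )
    return [l.strip().upper() for l in text.splitlines() if l.strip() and not l.startswith("#")]


def published_trial_phase_counts() -> pd.DataFrame:
    """Per-phase clinical-trial counts for selected repurposing candidates,
    compiled from public trial registries (drug, phase, n_trials)."""
    with importlib.resources.files("stemrx.data").joinpath(
        "trial_phase_counts.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Ct cards
# ---------------------------------------------------------------------------


def _gene_panel(cfg: SimulationConfig) -> list[str]:
    effect = list(cfg.effect_genes)
    filler = [f"G{i:03d}" for i in range(1, cfg.n_genes - len(effect) + 1)]
    panel = [g.upper() for g in effect] + filler
    if len(panel) != cfg.n_genes:
        raise ValueError("more effect genes than panel slots")
    return panel


def simulate_ct_cards(cfg: SimulationConfig) -> list[ArrayCard]:
    """Simulate array cards for a 2D-vs-3D comparison.

    Per gene, a baseline Ct uniform over ``baseline_ct_range``; 3D samples
    additionally shifted by the planted effect (negative shift = more RNA
    in 3D); i.i.d. Gaussian noise of ``noise_sd`` cycles on every
    measurement.  Cts above 40 are clipped to 40 and flagged undetected,
    mirroring the reader convention.  The panel is split round-robin over
    the three card platforms.
    """
    panel = _gene_panel(cfg)
    unknown = set(cfg.effect_genes) - set(panel)
    if unknown:
        raise ValueError(f"effect genes not in panel: {sorted(unknown)}")
    rng = cfg.rng(0)
    baseline = dict(zip(panel, rng.uniform(*cfg.baseline_ct_range, size=len(panel))))
    platforms = {g: list(Platform)[i % 3] for i, g in enumerate(panel)}

    cards: list[ArrayCard] = []
    for cond, prefix in ((Condition.TWO_D, "2D"), (Condition.THREE_D, "3D")):
        for rep in range(1, cfg.n_samples_per_group + 1):
            sample_id = f"{prefix}_rep{rep}"
            for plat in Platform:
                genes = [g for g in panel if platforms[g] is plat]
                if not genes:
                    continue
                mu = np.array(
                    [
                        baseline[g]
                        + (cfg.effect_genes.get(g, 0.0) if cond is Condition.THREE_D else 0.0)
                        for g in genes
                    ]
                )
                cts = mu + rng.normal(0.0, cfg.noise_sd, size=len(genes))
                cts = np.clip(cts, 1e-6, MAX_CYCLES)
                cards.append(
                    ArrayCard(
                        sample_id=sample_id,
                        condition=cond,
                        cell_line="SIM",
                        platform=plat,
                        measurements=[
                            CtMeasurement(gene=g, ct=float(c), detected=float(c) <= 35.0)
                            for g, c in zip(genes, cts)
                        ],
                    )
                )
    return cards


def cards_to_frame(cards: Sequence[ArrayCard]) -> pd.DataFrame:
    """Long-format table matching the ingestion schema."""
    rows = [
        {
            "sample": c.sample_id,
            "condition": c.condition.value,
            "cell_line": c.cell_line,
            "platform": c.platform.value,
            "gene": m.gene,
            "ct": f"{m.ct:.6f}" if m.detected or m.ct < MAX_CYCLES else "Undetermined",
        }
        for c in cards
        for m in c.measurements
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Interaction table, registry, side tables
# ---------------------------------------------------------------------------


def simulate_interaction_table(
    cfg: SimulationConfig, genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Sparse bipartite drug–gene table with publication/source counts.

    Each pair enters independently with probability ``edge_density``;
    publication counts are geometric (mean ≈ 3), source counts uniform on
    1..5.  Every drug is guaranteed at least one edge (a drug with no
    targets cannot exist in an interaction database).
    """
    if cfg.n_drugs < 1 or cfg.n_gene_targets < 1:
        raise ValueError("need at least one drug and one gene")
    rng = cfg.rng(1)
    drugs = [f"drug{i:03d}" for i in range(1, cfg.n_drugs + 1)]
    if genes is None:
        genes = [f"TGT{i:02d}" for i in range(1, cfg.n_gene_targets + 1)]
    genes = [g.upper() for g in genes]

    rows = []
    for d in drugs:
        hits = rng.random(len(genes)) < cfg.edge_density
        if not hits.any():
            hits[rng.integers(len(genes))] = True
        for g, h in zip(genes, hits):
            if h:
                rows.append(
                    {
                        "drug": d,
                        "gene": g,
                        "publication_count": int(rng.geometric(1 / 3.0)),
                        "source_count": int(rng.integers(1, 6)),
                    }
                )
    return pd.DataFrame(rows)


def simulate_trial_registry(
    cfg: SimulationConfig, drugs: Sequence[str]
) -> pd.DataFrame:
    """Trial registry extract: per-drug counts Poisson(``trial_rate``),
    phases/statuses/cancer types drawn from registry vocabulary.

    A ``1 − oncology_trial_fraction`` share of records carries an empty
    cancer type (non-oncology trials)."""
    if not list(drugs):
        raise ValueError("drug list is empty")
    rng = cfg.rng(2)
    rows = []
    n = 0
    for d in drugs:
        for _ in range(rng.poisson(cfg.trial_rate)):
            n += 1
            onc = rng.random() < cfg.oncology_trial_fraction
            rows.append(
                {
                    "trial_id": f"SIM{n:06d}",
                    "drug": d,
                    "phase": rng.choice(_PHASE_VOCAB, p=_PHASE_WEIGHTS),
                    "status": rng.choice(_STATUS_VOCAB, p=_STATUS_WEIGHTS),
                    "cancer_type": rng.choice(_CANCER_VOCAB) if onc else "",
                }
            )
    return pd.DataFrame(rows, columns=["trial_id", "drug", "phase", "status", "cancer_type"])


def simulate_redo_table(cfg: SimulationConfig, drugs: Sequence[str]) -> pd.DataFrame:
    rng = cfg.rng(3)
    cols = ["in_vitro", "in_vivo", "case_report", "observational", "trial_data"]
    probs = [0.8, 0.6, 0.3, 0.25, 0.5]
    return pd.DataFrame(
        [
            {"drug": d, **{c: int(rng.random() < p) for c, p in zip(cols, probs)}}
            for d in drugs
        ]
    )


def simulate_associations(
    cfg: SimulationConfig, genes: Sequence[str], disease: str = "cancer"
) -> pd.DataFrame:
    rng = cfg.rng(4)
    return pd.DataFrame(
        [
            {"gene": g.upper(), "disease": disease, "score": round(float(rng.uniform(0.05, 1.0)), 4)}
            for g in genes
        ]
    )


# ---------------------------------------------------------------------------
# Single-cell seeding (Poisson occupancy)
# ---------------------------------------------------------------------------


def poisson_single_cell_occupancy(lam: float) -> float:
    """P(a well receives at most one cell) = e^−λ (1 + λ).

    Single-cell seeding assays dilute cells so that wells rarely receive
    more than one; this is the quantity tuned to ≈ 0.9.
    """
    if lam < 0:
        raise ValueError("λ must be nonnegative")
    return math.exp(-lam) * (1.0 + lam)


def poisson_single_given_occupied(lam: float) -> float:
    """Conditional variant: P(exactly one cell | well not empty)."""
    if lam < 0:
        raise ValueError("λ must be nonnegative")
    if lam == 0:
        return 1.0
    return lam * math.exp(-lam) / (1.0 - math.exp(-lam))


def solve_seeding_rate(target: float = 0.9) -> float:
    """The λ at which P(X ≤ 1) equals ``target`` (monotone-decreasing root)."""
    if not (0.0 < target < 1.0):
        raise ValueError("target probability must lie in (0, 1)")
    return float(brentq(lambda l: poisson_single_cell_occupancy(l) - target, 1e-12, 50.0))


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------

#: Drug roster of the engineered bundle: (drug, targets hit, licensed cancer drug)
_ENGINEERED_DRUGS: list[tuple[str, list[str], bool]] = [
    ("imatinib", ["KIT", "ABCB1"], True),
    ("temozolomide", ["ABCB1"], True),
    ("dasatinib", ["KIT"], True),
    ("allopurinol", ["POU5F1"], False),
    ("phenytoin", ["POU5F1", "GABRB3"], False),
    ("propofol", ["GABRB3", "ABCB1"], False),
    ("verapamil", ["ABCC1", "ABCB1"], False),
    ("cyclosporine", ["ABCC1", "ABCB1"], False),
    ("simvastatin", ["ABCB1", "MTOR"], False),
    ("sirolimus", ["MTOR", "ABCB1"], False),
    ("disulfiram", ["ABCB1"], False),
    ("clarithromycin", ["ABCB1"], False),
    ("probucol", ["ABCG1"], False),
    ("hyaluronidase", ["CD44"], False),
    ("cilengitide", ["ITGB1"], False),
    ("methyl-beta-cyclodextrin", ["CAV1"], False),
    ("azacitidine", ["DNMT3B"], True),
    ("c1632", ["LIN28A"], False),
    ("sb-431542", ["LEFTY2"], False),
]

#: Hub-and-core association network of the engineered bundle: POU5F1 touches
#: 10 partners; {POU5F1, KIT, CAV1, ITGB1, CD44} form a complete core.
_ENGINEERED_EDGES: list[tuple[str, str, str]] = (
    [("POU5F1", g, "experimental") for g in ["KIT", "CAV1", "ITGB1", "CD44"]]
    + [
        ("KIT", "CAV1", "experimental"),
        ("KIT", "ITGB1", "curated"),
        ("KIT", "CD44", "experimental"),
        ("CAV1", "ITGB1", "experimental"),
        ("CAV1", "CD44", "curated"),
        ("ITGB1", "CD44", "experimental"),
    ]
    + [
        ("POU5F1", g, "textmining")
        for g in ["LIN28A", "DNMT3B", "ABCG1", "MTOR", "LEFTY2", "GABRB3"]
    ]
    + [("ABCB1", "ABCC1", "coexpression")]
)


def make_fixture_bundle(
    cfg: SimulationConfig, out_dir: str | Path, *, engineered: bool = False
) -> Path:
    """Write every pipeline input to ``out_dir`` and return that path.

    ``engineered=True`` swaps the random target/drug layer for the
    deterministic 21-target fixture in which exactly 13 targets (62%) have
    at least one interacting drug; the Ct layer stays simulated from
    ``cfg`` (effect genes are forced to panel members POU5F1 and ABCG1).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise NotADirectoryError(out)

    if engineered:
        cfg = SimulationConfig(
            **{
                **cfg.__dict__,
                "effect_genes": {"ABCG1": -3.0, "POU5F1": -3.0},
            }
        )
    cards = simulate_ct_cards(cfg)
    panel = _gene_panel(cfg)
    cards_to_frame(cards).to_csv(out / "cards.tsv", sep="\t", index=False)
    (out / "panel.txt").write_text("\n".join(panel) + "\n")

    if engineered:
        targets = packaged_target_panel()
        (out / "escsc_genes.txt").write_text("\n".join(targets) + "\n")
        inter = pd.DataFrame(
            [
                {
                    "drug": d,
                    "gene": g,
                    "publication_count": 1 + (i + j) % 7,
                    "source_count": 1 + (i * 3 + j) % 5,
                }
                for i, (d, genes, _) in enumerate(_ENGINEERED_DRUGS)
                for j, g in enumerate(genes)
            ]
        )
        drugs = [d for d, _, _ in _ENGINEERED_DRUGS]
        licence = [d for d, _, lic in _ENGINEERED_DRUGS if lic]
        edges = pd.DataFrame(_ENGINEERED_EDGES, columns=["a", "b", "evidence"])
        assoc_genes = targets
    else:
        rng = cfg.rng(5)
        targets = [f"TGT{i:02d}" for i in range(1, cfg.n_gene_targets + 1)]
        (out / "escsc_genes.txt").write_text("\n".join(targets) + "\n")
        inter = simulate_interaction_table(cfg, genes=targets)
        drugs = sorted(inter["drug"].unique())
        licence = [d for d in drugs if rng.random() < 0.25]
        pairs = [(a, b) for i, a in enumerate(targets) for b in targets[i + 1 :]]
        chosen = [p for p in pairs if rng.random() < cfg.edge_density]
        edges = pd.DataFrame(
            [
                (a, b, rng.choice(["experimental", "curated", "coexpression", "textmining"]))
                for a, b in chosen
            ],
            columns=["a", "b", "evidence"],
        )
        assoc_genes = targets

    inter.to_csv(out / "interactions.tsv", sep="\t", index=False)
    (out / "licence.txt").write_text("\n".join(licence) + ("\n" if licence else ""))
    simulate_trial_registry(cfg, drugs).to_csv(out / "registry.tsv", sep="\t", index=False)
    simulate_redo_table(cfg, drugs).to_csv(out / "redo.tsv", sep="\t", index=False)
    simulate_associations(cfg, assoc_genes).to_csv(out / "associations.tsv", sep="\t", index=False)
    edges.to_csv(out / "edges.tsv", sep="\t", index=False)

    manifest = [
        "# Fixture bundle",
        "",
        f"engineered: {engineered}",
        f"seed: {cfg.seed}",
        "",
        "| file | contents |",
        "| --- | --- |",
        "| cards.tsv | long-format Ct table (sample, condition, cell_line, platform, gene, ct) |",
        "| panel.txt | analysis gene panel, one symbol per line |",
        "| escsc_genes.txt | patient-derived stem-cell gene list (source 1) |",
        "| interactions.tsv | drug–gene interactions (drug, gene, publication_count, source_count) |",
        "| licence.txt | licensed cancer drugs, one per line |",
        "| registry.tsv | clinical-trial records (trial_id, drug, phase, status, cancer_type) |",
        "| redo.tsv | repurposing evidence flags (drug + five 0/1 columns) |",
        "| associations.tsv | target–disease association scores (gene, disease, score) |",
        "| edges.tsv | protein-association edge list (a, b, evidence) |",
    ]
    (out / "MANIFEST.md").write_text("\n".join(manifest) + "\n")
    return out
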