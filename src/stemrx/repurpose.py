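"""Drug-repurposing stage: interaction scoring, trial aggregation and the
candidate table.

Works from static TSV snapshots of the external resources a repurposing
screen consults — a drug–gene interaction table (DGIdb-style, with
publication and data-source counts), a target–disease association table
(Open-Targets-style scores in [0, 1]), a licensed-cancer-drug list, a
clinical-trial registry extract and a repurposing-evidence (ReDO-style)
table.  No live database is ever queried.

The drug–gene interaction score rewards well-documented, specific pairings:

    score = (publication count + data source count)
            × (mean genes-per-drug over all drugs / genes of this drug)
            × (mean drugs-per-gene over all genes / drugs of this gene)

so promiscuous drugs and heavily-drugged genes are down-weighted relative
to the database average.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .targets import TargetGene


class Phase(enum.IntEnum):
    """Clinical-trial phase, ordered so max() is the headline phase.

    OTHER (expanded access, N/A, observational…) never outranks a numbered
    phase.
    """

    OTHER = 0
    P1 = 1
    P1_2 = 2
    P2 = 3
    P2_3 = 4
    P3 = 5
    P4 = 6


_PHASE_LITERALS = {
    "other": Phase.OTHER,
    "phase 1": Phase.P1,
    "phase 1/2": Phase.P1_2,
    "phase 2": Phase.P2,
    "phase 2/3": Phase.P2_3,
    "phase 3": Phase.P3,
    "phase 4": Phase.P4,
}

_PHASE_LABELS = {v: k.title() if v is not Phase.OTHER else "Other" for k, v in _PHASE_LITERALS.items()}


def parse_phase(raw: str) -> Phase:
    try:
        return _PHASE_LITERALS[raw.strip().lower()]
    except KeyError:
        raise ValueError(f"malformed trial phase {raw!r}") from None


def normalise_drug(name: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Case-fold and strip a drug name; apply an optional synonym map.

    No fuzzy matching — a silent mismatch is worse than a miss.
    """
    key = name.strip().lower()
    if synonyms:
        key = synonyms.get(key, key)
    return key


@dataclass(frozen=True)
class DrugGeneInteraction:
    drug: str
    gene: str
    publication_count: int
    source_count: int
    interaction_score: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug", normalise_drug(self.drug))
        object.__setattr__(self, "gene", self.gene.strip().upper())
        if self.publication_count < 0 or self.source_count < 0:
            raise ValueError("publication/source counts must be nonnegative")


@dataclass(frozen=True)
class TargetDiseaseAssociation:
    gene: str
    disease: str
    assoc_score: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", self.gene.strip().upper())
        if not (0.0 <= self.assoc_score <= 1.0):
            raise ValueError(f"association score must lie in [0, 1]; got {self.assoc_score}")


@dataclass(frozen=True)
class TrialRecord:
    trial_id: str
    drug: str
    phase: Phase
    status: str
    cancer_type: str

    def __post_init__(self) -> None:
        if not self.trial_id:
            raise ValueError("trial_id must be non-empty")
        object.__setattr__(self, "drug", normalise_drug(self.drug))


@dataclass(frozen=True)
class RedoEvidence:
    """Which evidence categories back a repurposing candidate."""

    drug: str
    has_in_vitro: bool = False
    has_in_vivo: bool = False
    has_case_report: bool = False
    has_observational: bool = False
    has_trial_data: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug", normalise_drug(self.drug))


@dataclass
class CandidateRow:
    """One drug's line in the candidate report."""

    drug: str
    targets: list[str]
    is_cancer_drug: bool
    trial_count: int
    max_phase: Phase | None
    phase_hist: dict[str, int]
    status_hist: dict[str, int]
    cancer_type_hist: dict[str, int]
    support_score: int
    interaction_scores: dict[str, float]
    off_patent: bool | None = None
    in_oncology_trials: bool = False
    disease_targets: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Interaction scoring
# ---------------------------------------------------------------------------


def score_interaction_table(table: pd.DataFrame) -> pd.DataFrame:
    """Attach ``interaction_score`` to every edge of a drug–gene table.

    Expects columns drug, gene, publication_count, source_count; drugs are
    case-folded, genes upper-cased, and (drug, gene) must be unique.
    """
    if table.empty:
        raise ValueError("interaction table is empty")
    t = table.copy()
    t["drug"] = t["drug"].map(normalise_drug)
    t["gene"] = t["gene"].str.strip().str.upper()
    if t.duplicated(subset=["drug", "gene"]).any():
        dup = t[t.duplicated(subset=["drug", "gene"])].iloc[0]
        raise ValueError(f"duplicate interaction ({dup['drug']}, {dup['gene']})")

    genes_per_drug = t.groupby("drug")["gene"].nunique()
    drugs_per_gene = t.groupby("gene")["drug"].nunique()
    assert (genes_per_drug > 0).all() and (drugs_per_gene > 0).all()
    mean_gpd = genes_per_drug.mean()
    mean_dpg = drugs_per_gene.mean()

    t["interaction_score"] = (
        (t["publication_count"].astype(float) + t["source_count"].astype(float))
        * (mean_gpd / t["drug"].map(genes_per_drug))
        * (mean_dpg / t["gene"].map(drugs_per_gene))
    )
    return t


def interaction_score(edge: DrugGeneInteraction, table: pd.DataFrame) -> float:
    """Score a single edge against the full table (see module docstring)."""
    scored = score_interaction_table(table)
    hit = scored[(scored["drug"] == edge.drug) & (scored["gene"] == edge.gene)]
    if hit.empty:
        raise ValueError(f"edge ({edge.drug}, {edge.gene}) not present in table")
    return float(hit["interaction_score"].iloc[0])


def expand_polypharmacology(
    drug: str,
    table: pd.DataFrame,
    assoc: Sequence[TargetDiseaseAssociation],
    disease: str,
) -> list[str]:
    """Disease-relevant targets of a drug, strongest association first.

    Returns every gene the drug interacts with that carries an association
    record for ``disease``; ties in score break alphabetically.
    """
    if not disease:
        raise ValueError("disease term must be non-empty")
    drug = normalise_drug(drug)
    drug_genes = {
        g.strip().upper()
        for g in table.loc[table["drug"].map(normalise_drug) == drug, "gene"]
    }
    scores = {
        a.gene: a.assoc_score
        for a in assoc
        if a.disease.strip().lower() == disease.strip().lower() and a.gene in drug_genes
    }
    return sorted(scores, key=lambda g: (-scores[g], g))


def classify_cancer_drug(drug: str, licence_table: Iterable[str]) -> bool:
    """Case-insensitive membership in the licensed-cancer-drug list."""
    return normalise_drug(drug) in {normalise_drug(d) for d in licence_table}


def aggregate_trials(drug: str, registry: Sequence[TrialRecord]) -> dict:
    """Trial count, phase/status/cancer-type histograms and max phase for a drug.

    The phase histogram keys use the registry literals ("Phase 1", …,
    "Other"); ``max_phase`` is None when the drug has no trials.  Every
    record contributes exactly once to each histogram, so the three
    histograms all sum to the trial count.
    """
    drug = normalise_drug(drug)
    records = [r for r in registry if r.drug == drug]
    phase_hist = Counter(_PHASE_LABELS[r.phase] for r in records)
    status_hist = Counter(r.status for r in records)
    cancer_hist = Counter(r.cancer_type for r in records)
    max_phase = max((r.phase for r in records), default=None)
    return {
        "trial_count": len(records),
        "max_phase": max_phase,
        "phase_hist": dict(phase_hist),
        "status_hist": dict(status_hist),
        "cancer_type_hist": dict(cancer_hist),
        "in_oncology_trials": any(r.cancer_type.strip() for r in records),
    }


def support_score(evidence: RedoEvidence) -> int:
    """Number of evidence categories (0–5) backing the candidate."""
    return sum(
        [
            evidence.has_in_vitro,
            evidence.has_in_vivo,
            evidence.has_case_report,
            evidence.has_observational,
            evidence.has_trial_data,
        ]
    )


# ---------------------------------------------------------------------------
# Candidate table
# ---------------------------------------------------------------------------


def build_candidate_table(
    targets: Sequence[TargetGene],
    table: pd.DataFrame,
    licence: Iterable[str],
    registry: Sequence[TrialRecord],
    redo: Sequence[RedoEvidence],
    assoc: Sequence[TargetDiseaseAssociation] = (),
    *,
    disease: str = "cancer",
    min_targets: int = 1,
) -> tuple[list[CandidateRow], dict]:
    """Assemble the per-drug candidate report and headline summary.

    One row per drug hitting at least ``min_targets`` of the prioritised
    target set; target lists are restricted to that set.  Side effect:
    each :class:`TargetGene`'s ``has_drug`` flag is set.  Returns
    ``(rows, summary)`` where the summary carries the headline counts
    (targets covered, cancer / non-cancer split, per-gene drug counts,
    drugs in oncology trials).
    """
    target_syms = {t.symbol for t in targets}
    scored = score_interaction_table(table) if not table.empty else table
    licence_set = {normalise_drug(d) for d in licence}
    redo_by_drug = {e.drug: e for e in redo}

    rows: list[CandidateRow] = []
    genes_hit: Counter[str] = Counter()
    if not scored.empty:
        on_target = scored[scored["gene"].isin(target_syms)]
        for drug, sub in on_target.groupby("drug", sort=True):
            hit = sorted(sub["gene"].unique())
            if len(hit) < min_targets:
                continue
            agg = aggregate_trials(drug, registry)
            ev = redo_by_drug.get(drug, RedoEvidence(drug=drug))
            rows.append(
                CandidateRow(
                    drug=str(drug),
                    targets=hit,
                    is_cancer_drug=drug in licence_set,
                    trial_count=agg["trial_count"],
                    max_phase=agg["max_phase"],
                    phase_hist=agg["phase_hist"],
                    status_hist=agg["status_hist"],
                    cancer_type_hist=agg["cancer_type_hist"],
                    support_score=support_score(ev),
                    interaction_scores={
                        g: float(s) for g, s in zip(sub["gene"], sub["interaction_score"])
                    },
                    in_oncology_trials=agg["in_oncology_trials"],
                    disease_targets=expand_polypharmacology(drug, scored, assoc, disease)
                    if assoc
                    else [],
                )
            )
            genes_hit.update(hit)

    covered = {g for g in genes_hit}
    for t in targets:
        t.has_drug = t.symbol in covered

    n_targets = len(target_syms)
    n_with_drug = len(covered & target_syms)
    n_cancer = sum(1 for r in rows if r.is_cancer_drug)
    summary = {
        "n_targets": n_targets,
        "n_targets_with_drug": n_with_drug,
        "pct_targets_with_drug": round(100.0 * n_with_drug / n_targets) if n_targets else 0,
        "n_drugs": len(rows),
        "n_cancer_drugs": n_cancer,
        "n_non_cancer_drugs": len(rows) - n_cancer,
        "n_drugs_per_target": {g: int(c) for g, c in sorted(genes_hit.items())},
        "n_drugs_in_oncology_trials": sum(1 for r in rows if r.in_oncology_trials),
    }
    return rows, summary


def candidate_frame(rows: Sequence[CandidateRow]) -> pd.DataFrame:
    """Candidate rows as the report-shaped table."""

    def fmt_hist(h: Mapping[str, int]) -> str:
        return ", ".join(f"{k} ({v})" for k, v in sorted(h.items()))

    return pd.DataFrame(
        [
            {
                "drug": r.drug,
                "targets": ", ".join(r.targets),
                "cancer_drug": "Y" if r.is_cancer_drug else "N",
                "trial_count": r.trial_count,
                "max_phase": _PHASE_LABELS[r.max_phase] if r.max_phase is not None else "NA",
                "phase_hist": fmt_hist(r.phase_hist),
                "status_hist": fmt_hist(r.status_hist),
                "cancer_type_hist": fmt_hist(r.cancer_type_hist),
                "support_score": r.support_score,
                "max_interaction_score": max(r.interaction_scores.values(), default=0.0),
            }
            for r in rows
        ]
    )


# ---------------------------------------------------------------------------
# Snapshot I/O
# ---------------------------------------------------------------------------


def read_interaction_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"drug", "gene", "publication_count", "source_count"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_licence_list(path: str | Path) -> set[str]:
    return {
        normalise_drug(line)
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }


def read_trial_registry(path: str | Path) -> list[TrialRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"trial_id", "drug", "phase", "status", "cancer_type"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for r in df.itertuples():
        try:
            phase = parse_phase(r.phase)
        except ValueError as exc:
            raise ValueError(f"{path}: record {r.trial_id}: {exc}") from None
        out.append(
            TrialRecord(
                trial_id=r.trial_id,
                drug=r.drug,
                phase=phase,
                status=r.status,
                cancer_type=r.cancer_type,
            )
        )
    return out


def read_redo_table(path: str | Path) -> list[RedoEvidence]:
    df = pd.read_csv(path, sep="\t")
    cols = ["in_vitro", "in_vivo", "case_report", "observational", "trial_data"]
    missing = {"drug", *cols} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        RedoEvidence(
            drug=r.drug,
            has_in_vitro=bool(r.in_vitro),
            has_in_vivo=bool(r.in_vivo),
            has_case_report=bool(r.case_report),
            has_observational=bool(r.observational),
            has_trial_data=bool(r.trial_data),
        )
        for r in df.itertuples()
    ]


def read_associations(path: str | Path) -> list[TargetDiseaseAssociation]:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "disease", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        TargetDiseaseAssociation(gene=r.gene, disease=r.disease, assoc_score=float(r.score))
        for r in df.itertuples()
    ]
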