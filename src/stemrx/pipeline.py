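"""End-to-end orchestration: normalise → DE → targets → repurpose → report.

A run consumes a bundle directory of input files (see
:func:`stemrx.synthetic_data.make_fixture_bundle` for the layout), applies
the analysis thresholds, and writes every intermediate table plus a
``summary.json`` of headline counts to the output directory.  Runs are
fully deterministic functions of (inputs, config); the effective
configuration and input checksums are echoed for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ct_model, diff_expr, repurpose, targets as targets_mod
from .ct_model import CT_DETECTION_LIMIT, CT_HIGH_EXPRESSION, Condition
from .diff_expr import CtExclusionMode

log = logging.getLogger("stemrx")


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    bundle_dir: Path
    out_dir: Path
    q_cut: float = 0.1
    dct_cut: float = 2.0
    ct_detect: float = CT_DETECTION_LIMIT
    ct_high: float = CT_HIGH_EXPRESSION
    ct_exclusion_mode: str = "both"        # or "group_a"
    normalisation_scope: str = "joint"     # or "per_card"
    detected_only: bool = False
    disease: str = "cancer"
    seed: int = 0

    def __post_init__(self) -> None:
        self.bundle_dir = Path(self.bundle_dir)
        self.out_dir = Path(self.out_dir)
        for name in ("q_cut", "dct_cut", "ct_detect", "ct_high"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.ct_exclusion_mode not in ("both", "group_a"):
            raise ValueError("ct_exclusion_mode must be 'both' or 'group_a'")
        if self.normalisation_scope not in ("joint", "per_card"):
            raise ValueError("normalisation_scope must be 'joint' or 'per_card'")

    def path(self, name: str) -> Path:
        p = self.bundle_dir / name
        if not p.exists():
            raise FileNotFoundError(f"required input missing from bundle: {p}")
        return p


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"[{name}] {exc}") from exc

        return wrapper

    return deco


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


@_stage("normalise")
def stage_normalise(cfg: RunConfig) -> tuple[pd.DataFrame, dict, dict]:
    """Read cards and produce the ΔCt matrix, group map and per-group mean Ct."""
    cards = ct_model.read_ct_table(cfg.path("cards.tsv"))
    panel = targets_mod.read_gene_list(cfg.path("panel.txt"))
    by_sample: dict[str, list[ct_model.ArrayCard]] = {}
    groups: dict[str, str] = {}
    for c in cards:
        by_sample.setdefault(c.sample_id, []).append(c)
        groups[c.sample_id] = c.condition.value

    vectors = []
    for sid, sample_cards in sorted(by_sample.items()):
        if cfg.normalisation_scope == "joint":
            vectors.append(
                ct_model.global_mean_normalise_sample(
                    sample_cards, panel=set(panel) & {m.gene for sc in sample_cards for m in sc.measurements},
                    detected_only=cfg.detected_only,
                )
            )
        else:
            per_card = [
                ct_model.global_mean_normalise(
                    sc, panel=set(panel) & sc.genes, detected_only=cfg.detected_only
                )
                for sc in sample_cards
                if set(panel) & sc.genes
            ]
            merged: dict[str, float] = {}
            for v in per_card:
                merged.update(v.values)
            vectors.append(ct_model.DeltaCtVector(sample_id=sid, values=merged))

    dct = ct_model.dct_matrix(vectors)

    # per-gene mean raw Ct within each condition, for the detection filter
    raw: dict[str, dict[str, list[float]]] = {}
    for c in cards:
        for m in c.measurements:
            raw.setdefault(m.gene, {}).setdefault(c.condition.value, []).append(m.ct)
    mean_ct = {
        g: (
            sum(v.get("2D", [40.0])) / max(len(v.get("2D", [1])), 1),
            sum(v.get("3D", [40.0])) / max(len(v.get("3D", [1])), 1),
        )
        for g, v in raw.items()
    }

    dct.to_csv(cfg.out_dir / "dct_matrix.tsv", sep="\t")
    return dct, groups, mean_ct


@_stage("diff_expr")
def stage_de(
    cfg: RunConfig, dct: pd.DataFrame, groups: dict, mean_ct: dict
) -> list[diff_expr.DEResult]:
    results = diff_expr.moderated_de(dct, groups)
    results = diff_expr.apply_significance_filter(
        results,
        {g: mean_ct[g] for g in (r.gene for r in results)},
        q_cut=cfg.q_cut,
        dct_cut=cfg.dct_cut,
        ct_detect=cfg.ct_detect,
        mode=CtExclusionMode(cfg.ct_exclusion_mode),
    )
    diff_expr.results_frame(results).to_csv(cfg.out_dir / "de_results.tsv", sep="\t", index=False)
    diff_expr.volcano_table(results, q_cut=cfg.q_cut, dct_cut=cfg.dct_cut).to_csv(
        cfg.out_dir / "volcano.tsv", sep="\t", index=False
    )

    tiers = {
        grp: {g: ct_model.classify_tier(min(mean_ct[g][i], 40.0)) for g in mean_ct}
        for i, grp in enumerate(("2D", "3D"))
    }
    summary = diff_expr.detection_set_analysis(tiers["2D"], tiers["3D"])
    (cfg.out_dir / "detection_summary.json").write_text(
        json.dumps(dataclasses.asdict(summary), indent=2, sort_keys=True) + "\n"
    )
    return results


@_stage("targets")
def stage_targets(
    cfg: RunConfig, results: list[diff_expr.DEResult]
) -> tuple[list[targets_mod.TargetGene], list[targets_mod.NetworkEdge]]:
    de_up = [r.gene for r in results if r.significant and r.diff > 0]
    escsc = targets_mod.read_gene_list(cfg.path("escsc_genes.txt"))
    merged = targets_mod.merge_target_sources(de_up, escsc)
    edges = targets_mod.read_edge_list(cfg.path("edges.tsv"))
    return merged, edges


@_stage("repurpose")
def stage_repurpose(
    cfg: RunConfig,
    target_list: list[targets_mod.TargetGene],
    edges: list[targets_mod.NetworkEdge],
) -> dict:
    table = repurpose.read_interaction_table(cfg.path("interactions.tsv"))
    licence = repurpose.read_licence_list(cfg.path("licence.txt"))
    registry = repurpose.read_trial_registry(cfg.path("registry.tsv"))
    redo = repurpose.read_redo_table(cfg.path("redo.tsv"))
    assoc = repurpose.read_associations(cfg.path("associations.tsv"))

    rows, summary = repurpose.build_candidate_table(
        target_list, table, licence, registry, redo, assoc, disease=cfg.disease
    )
    repurpose.candidate_frame(rows).to_csv(cfg.out_dir / "candidates.tsv", sep="\t", index=False)
    targets_mod.targets_frame(target_list, edges).to_csv(
        cfg.out_dir / "targets.tsv", sep="\t", index=False
    )
    universe = [t.symbol for t in target_list]
    cores = targets_mod.mutually_interacting_core(edges, universe, k=2)
    components = targets_mod.connected_core(edges, universe)
    summary["largest_mutually_interacting_core"] = sorted(cores[0]) if cores else []
    summary["largest_connected_core"] = sorted(components[0]) if components else []
    return summary


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the summary dict (also written to disk)."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("cards.tsv", "panel.txt", "escsc_genes.txt", "interactions.tsv"):
        p = cfg.bundle_dir / name
        if p.exists():  # a missing input fails inside its owning stage, by name
            log.info("input %s sha256=%s", name, _checksum(p))
    log.info(
        "thresholds: q<%s |dCt|>%s detect<=%s high<%s exclusion=%s scope=%s",
        cfg.q_cut, cfg.dct_cut, cfg.ct_detect, cfg.ct_high,
        cfg.ct_exclusion_mode, cfg.normalisation_scope,
    )

    dct, groups, mean_ct = stage_normalise(cfg)
    results = stage_de(cfg, dct, groups, mean_ct)
    target_list, edges = stage_targets(cfg, results)
    summary = stage_repurpose(cfg, target_list, edges)

    summary["n_genes_tested"] = len(results)
    summary["n_significant"] = sum(r.significant for r in results)
    summary["n_increased_3d"] = sum(r.significant and r.diff > 0 for r in results)

    effective = {
        k: str(v) if isinstance(v, Path) else v for k, v in dataclasses.asdict(cfg).items()
    }
    (cfg.out_dir / "config.json").write_text(json.dumps(effective, indent=2, sort_keys=True) + "\n")
    (cfg.out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def summarise(out_dir: str | Path) -> str:
    """Human-readable headline counts recomputed from a report bundle."""
    out_dir = Path(out_dir)
    summary_path = out_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.json in {out_dir}")
    s = json.loads(summary_path.read_text())
    lines = [
        f"targets prioritised: {s['n_targets']}",
        f"targets with >=1 drug: {s['n_targets_with_drug']}/{s['n_targets']} "
        f"({s['pct_targets_with_drug']}%)",
        f"candidate drugs: {s['n_drugs']} "
        f"(cancer {s['n_cancer_drugs']} / non-cancer {s['n_non_cancer_drugs']})",
        f"drugs in oncology trials: {s['n_drugs_in_oncology_trials']}",
    ]
    cand_path = out_dir / "candidates.tsv"
    if cand_path.exists():
        cand = pd.read_csv(cand_path, sep="\t")
        if not cand.empty:
            top = cand.sort_values("max_interaction_score", ascending=False).iloc[0]
            lines.append(
                f"top candidate by interaction score: {top['drug']} "
                f"({top['max_interaction_score']:.3g} on {top['targets']})"
            )
    return "\n".join(lines)
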