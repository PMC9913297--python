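"""Data model and deterministic arithmetic for qPCR-array Ct tables.

A TaqMan-style low-density array card reports, per sample and per platform
(pluripotency, Wnt-pathway or ABC-transporter panels), one cycle-threshold
(Ct) value per gene.  Lower Ct means more template RNA.  This module handles
ingestion of long-format Ct tables, global-mean normalisation to ΔCt,
comparative-Ct fold changes (2^-ΔΔCt), expression tiering, and the two
self-renewal assay efficiencies (spheroid- and colony-forming).

Conventions
-----------
* Thermal cyclers run 40 cycles; a reaction that never crosses threshold
  ("Undetermined") is stored as Ct = 40.0 and flagged ``detected=False``.
* Detection: Ct <= 35 counts as detected; Ct > 35 is treated as absent.
* Tiers partition the Ct axis: HIGH (< 25), EXPRESSED ([25, 35]),
  NOT_DETECTED (> 35).  The closed interval at both boundaries makes the
  partition exhaustive.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

MAX_CYCLES = 40.0
CT_DETECTION_LIMIT = 35.0
CT_HIGH_EXPRESSION = 25.0

#: Endogenous-control assays present on the array cards.  These are excluded
#: from the analysis panel and from global-mean normalisation.  PPIA is the
#: validation housekeeping gene; the remainder are the usual card controls.
DEFAULT_ENDOGENOUS_CONTROLS = frozenset({"PPIA", "18S", "GAPDH", "GUSB", "HPRT1"})


class Condition(enum.Enum):
    """Culture condition of the profiled cells."""

    TWO_D = "2D"
    THREE_D = "3D"


class Platform(enum.Enum):
    """Array-card platform (which gene panel the card carries)."""

    PLURIPOTENCY = "pluripotency"
    WNT = "wnt"
    ABC = "abc"


class ExpressionTier(enum.Enum):
    HIGH = "high"
    EXPRESSED = "expressed"
    NOT_DETECTED = "not_detected"


@dataclass(frozen=True)
class CtMeasurement:
    """One gene's cycle-threshold value on a card."""

    gene: str
    ct: float
    detected: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", self.gene.strip().upper())
        if not (0.0 < self.ct <= MAX_CYCLES):
            raise ValueError(
                f"Ct for {self.gene} must lie in (0, {MAX_CYCLES}]; got {self.ct}"
            )


@dataclass
class ArrayCard:
    """One sample's panel of gene → Ct measurements."""

    sample_id: str
    condition: Condition
    cell_line: str
    platform: Platform
    measurements: list[CtMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        genes = [m.gene for m in self.measurements]
        if len(genes) != len(set(genes)):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise ValueError(
                f"duplicate gene symbols on card {self.sample_id}/"
                f"{self.platform.value}: {dupes}"
            )

    @property
    def genes(self) -> set[str]:
        return {m.gene for m in self.measurements}

    def ct_of(self, gene: str) -> float:
        gene = gene.strip().upper()
        for m in self.measurements:
            if m.gene == gene:
                return m.ct
        raise KeyError(f"gene {gene} not on card {self.sample_id}/{self.platform.value}")

    def analysis_genes(
        self, controls: frozenset[str] = DEFAULT_ENDOGENOUS_CONTROLS
    ) -> set[str]:
        """Panel genes excluding endogenous controls."""
        return {g for g in self.genes if g not in controls}


@dataclass(frozen=True)
class DeltaCtVector:
    """Per-sample ΔCt values: target Ct minus the sample's global-mean Ct."""

    sample_id: str
    values: dict[str, float]


@dataclass(frozen=True)
class AssayCounts:
    """Well/colony counts from the single-cell self-renewal assays."""

    wells_seeded: int = 0
    wells_with_progeny: int = 0
    colonies: int = 0
    cells_seeded: int = 0

    def __post_init__(self) -> None:
        for name in ("wells_seeded", "wells_with_progeny", "colonies", "cells_seeded"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.wells_with_progeny > self.wells_seeded:
            raise ValueError("wells_with_progeny cannot exceed wells_seeded")


# ---------------------------------------------------------------------------
# Ingestion
# ---------------------------------------------------------------------------

_CONDITION_ALIASES = {
    "2D": Condition.TWO_D,
    "TWO_D": Condition.TWO_D,
    "3D": Condition.THREE_D,
    "THREE_D": Condition.THREE_D,
}

_PLATFORM_ALIASES = {
    "PLURIPOTENCY": Platform.PLURIPOTENCY,
    "WNT": Platform.WNT,
    "ABC": Platform.ABC,
}


def _parse_ct(raw: object) -> tuple[float, bool]:
    """Map a raw Ct cell to (ct, detected).

    Non-numeric entries (e.g. "Undetermined") become Ct = 40, undetected;
    numeric Ct above the detection limit is kept but flagged undetected.
    """
    try:
        ct = float(raw)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return MAX_CYCLES, False
    if math.isnan(ct):
        return MAX_CYCLES, False
    return ct, ct <= CT_DETECTION_LIMIT


def read_ct_table(path: str | Path, *, sep: str | None = None) -> list[ArrayCard]:
    """Read a long-format Ct table into one :class:`ArrayCard` per
    (sample, platform).

    The file must carry columns ``sample, condition, platform, gene, ct``
    (``cell_line`` optional).  ``sep=None`` infers TSV/CSV from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sample", "condition", "platform", "gene", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "cell_line" not in df.columns:
        df["cell_line"] = ""

    dup = df.duplicated(subset=["sample", "platform", "gene"], keep=False)
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            "duplicate measurement for (sample, platform, gene) = "
            f"({first['sample']}, {first['platform']}, {first['gene']})"
        )

    cards: list[ArrayCard] = []
    for (sample, platform), sub in df.groupby(["sample", "platform"], sort=True):
        cond_raw = sub["condition"].iloc[0].strip().upper()
        if cond_raw not in _CONDITION_ALIASES:
            raise ValueError(f"unknown condition label {cond_raw!r} for sample {sample}")
        plat_raw = str(platform).strip().upper()
        if plat_raw not in _PLATFORM_ALIASES:
            raise ValueError(f"unknown platform label {platform!r} for sample {sample}")
        meas = [
            CtMeasurement(gene=row.gene, ct=ct, detected=det)
            for row in sub.itertuples()
            for ct, det in [_parse_ct(row.ct)]
        ]
        cards.append(
            ArrayCard(
                sample_id=str(sample),
                condition=_CONDITION_ALIASES[cond_raw],
                cell_line=str(sub["cell_line"].iloc[0]),
                platform=_PLATFORM_ALIASES[plat_raw],
                measurements=meas,
            )
        )
    return cards


# ---------------------------------------------------------------------------
# Normalisation and comparative Ct
# ---------------------------------------------------------------------------


def global_mean_normalise(
    card: ArrayCard,
    panel: Iterable[str],
    *,
    detected_only: bool = False,
) -> DeltaCtVector:
    """Normalise one card against the global mean of the panel genes.

    ΔCt(g) = Ct(g) − mean(Ct over panel).  By default the mean includes
    undetected genes at their stored Ct of 40; ``detected_only=True``
    restricts the mean to detected measurements.
    """
    panel = {g.strip().upper() for g in panel}
    if not panel:
        raise ValueError("normalisation panel is empty")
    missing = sorted(panel - card.genes)
    if missing:
        raise ValueError(
            f"panel genes absent from card {card.sample_id}/{card.platform.value}: {missing}"
        )
    by_gene = {m.gene: m for m in card.measurements}
    mean_pool = [
        by_gene[g].ct
        for g in panel
        if not detected_only or by_gene[g].detected
    ]
    if not mean_pool:
        raise ValueError("no detected panel genes to normalise against")
    mean_ct = sum(mean_pool) / len(mean_pool)
    values = {g: by_gene[g].ct - mean_ct for g in sorted(panel)}
    return DeltaCtVector(sample_id=card.sample_id, values=values)


def global_mean_normalise_sample(
    cards: Sequence[ArrayCard],
    panel: Iterable[str],
    *,
    detected_only: bool = False,
) -> DeltaCtVector:
    """Joint normalisation across a sample's cards (all platforms pooled).

    Targets on different array platforms become directly comparable when all
    cards of a sample share one global mean.  All cards must belong to the
    same sample.
    """
    if not cards:
        raise ValueError("no cards supplied")
    sample_ids = {c.sample_id for c in cards}
    if len(sample_ids) != 1:
        raise ValueError(f"cards span multiple samples: {sorted(sample_ids)}")
    panel = {g.strip().upper() for g in panel}
    if not panel:
        raise ValueError("normalisation panel is empty")
    by_gene: dict[str, CtMeasurement] = {}
    for card in cards:
        for m in card.measurements:
            if m.gene in by_gene:
                raise ValueError(
                    f"gene {m.gene} appears on multiple cards of sample {card.sample_id}"
                )
            by_gene[m.gene] = m
    missing = sorted(panel - set(by_gene))
    if missing:
        raise ValueError(f"panel genes absent from sample {cards[0].sample_id}: {missing}")
    pool = [by_gene[g].ct for g in panel if not detected_only or by_gene[g].detected]
    if not pool:
        raise ValueError("no detected panel genes to normalise against")
    mean_ct = sum(pool) / len(pool)
    return DeltaCtVector(
        sample_id=cards[0].sample_id,
        values={g: by_gene[g].ct - mean_ct for g in sorted(panel)},
    )


def comparative_ct(
    ct_target_sample: float,
    ct_control_gene_sample: float,
    ct_target_calibrator: float,
    ct_control_gene_calibrator: float,
) -> float:
    """Fold change by the comparative Ct method, 2^-ΔΔCt.

    ΔΔCt = (target − control gene) in the sample minus the same difference in
    the calibrator sample.  A ΔΔCt of −1 therefore doubles expression.
    """
    for v in (
        ct_target_sample,
        ct_control_gene_sample,
        ct_target_calibrator,
        ct_control_gene_calibrator,
    ):
        if not math.isfinite(v):
            raise ValueError("all four Ct values must be finite")
    ddct = (ct_target_sample - ct_control_gene_sample) - (
        ct_target_calibrator - ct_control_gene_calibrator
    )
    return 2.0 ** (-ddct)


def classify_tier(ct: float) -> ExpressionTier:
    """Assign a Ct value to its expression tier.

    HIGH below 25 cycles, EXPRESSED on [25, 35], NOT_DETECTED above 35.
    """
    if not (0.0 < ct <= MAX_CYCLES):
        raise ValueError(f"Ct must lie in (0, {MAX_CYCLES}]; got {ct}")
    if ct < CT_HIGH_EXPRESSION:
        return ExpressionTier.HIGH
    if ct <= CT_DETECTION_LIMIT:
        return ExpressionTier.EXPRESSED
    return ExpressionTier.NOT_DETECTED


def spheroid_forming_efficiency(counts: AssayCounts) -> float:
    """SFE (%) = wells containing a spheroid / wells seeded with one cell × 100."""
    if counts.wells_seeded <= 0:
        raise ValueError("wells_seeded must be positive")
    return 100.0 * counts.wells_with_progeny / counts.wells_seeded


def colony_forming_efficiency(counts: AssayCounts) -> float:
    """CFE (%) = colonies in the field of view / cells seeded × 100."""
    if counts.cells_seeded <= 0:
        raise ValueError("cells_seeded must be positive")
    return 100.0 * counts.colonies / counts.cells_seeded


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------


def dct_matrix(vectors: Sequence[DeltaCtVector]) -> pd.DataFrame:
    """Stack per-sample ΔCt vectors into a genes × samples DataFrame."""
    if not vectors:
        raise ValueError("no ΔCt vectors supplied")
    return pd.DataFrame({v.sample_id: pd.Series(v.values) for v in vectors}).sort_index()


def tier_table(cards: Mapping[str, ArrayCard] | Sequence[ArrayCard]) -> pd.DataFrame:
    """Genes × samples table of expression-tier labels."""
    if not isinstance(cards, Mapping):
        cards = {c.sample_id: c for c in cards}
    cols = {
        sid: pd.Series({m.gene: classify_tier(m.ct).value for m in card.measurements})
        for sid, card in cards.items()
    }
    return pd.DataFrame(cols).sort_index()
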