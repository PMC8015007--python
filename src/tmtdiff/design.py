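"""Experiment design summary derived from the annotation table."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from tmtdiff.errors import AnnotationError

REFERENCE_CONDITION = "Norm"

ANNOTATION_COLUMNS = [
    "Run",
    "Channel",
    "Condition",
    "BioReplicate",
    "Mixture",
    "TechRepMixture",
]


@dataclass
class ExperimentDesign:
    """The mixture / technical-replicate / condition / replicate structure.

    Attributes
    ----------
    n_mixtures:
        Number of distinct mixtures M.
    techreps_per_mixture:
        Mapping mixture -> number of technical replicate runs T for that
        mixture (may vary between mixtures).
    conditions:
        Sorted biological conditions, excluding the reserved reference label.
    bioreps:
        Mapping ``(mixture, condition) -> number of biological replicates``.
    has_reference:
        True when at least one channel carries the reserved ``"Norm"`` label.
    balanced:
        True when every condition has the same replicate count in every
        mixture.
    """

    n_mixtures: int
    techreps_per_mixture: dict = field(default_factory=dict)
    conditions: list = field(default_factory=list)
    bioreps: dict = field(default_factory=dict)
    has_reference: bool = False
    balanced: bool = True

    @property
    def max_techreps(self) -> int:
        return max(self.techreps_per_mixture.values(), default=1)

    @classmethod
    def from_annotation(cls, annotation: pd.DataFrame) -> "ExperimentDesign":
        ann = annotation
        missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
        if missing:
            raise AnnotationError(f"annotation lacks required columns: {missing}")
        mixtures = sorted(ann["Mixture"].astype(str).unique())
        techreps = {
            m: int(g["TechRepMixture"].nunique())
            for m, g in ann.assign(Mixture=ann["Mixture"].astype(str)).groupby("Mixture")
        }
        endo = ann[ann["Condition"].astype(str) != REFERENCE_CONDITION]
        conditions = sorted(endo["Condition"].astype(str).unique())
        bioreps = {}
        for (m, c), g in endo.groupby(
            [endo["Mixture"].astype(str), endo["Condition"].astype(str)]
        ):
            bioreps[(m, c)] = int(g["BioReplicate"].nunique())
        counts = set()
        for m in mixtures:
            for c in conditions:
                counts.add(bioreps.get((m, c), 0))
        balanced = len(counts) <= 1
        has_reference = bool(
            (ann["Condition"].astype(str) == REFERENCE_CONDITION).any()
        )
        return cls(
            n_mixtures=len(mixtures),
            techreps_per_mixture=techreps,
            conditions=conditions,
            bioreps=bioreps,
            has_reference=has_reference,
            balanced=balanced,
        )
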