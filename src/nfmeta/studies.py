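"""Containers for per-study expression data.

A *study* is one two-phenotype microarray comparison: a log2 probe-by-sample
intensity matrix, a phenotype label per sample, the species, and a
probe-to-gene map used later to collapse probes onto gene identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

VALID_SPECIES = ("human", "mouse")


@dataclass
class ExpressionStudy:
    """One normalized two-group expression study.

    Parameters
    ----------
    study_id
        Short unique label, e.g. an accession.
    species
        ``"human"`` or ``"mouse"``.
    matrix
        Log2 intensities, probes (rows, unique index) by samples (columns).
    groups
        Phenotype label per sample (index = sample IDs); exactly two levels,
        both non-empty.
    probe_map
        Probe ID -> gene ID (index = probe IDs). Probes absent from the map
        are dropped at collapse time with a logged count.
    comparison
        Ordered pair ``(group_a, group_b)``; effect sizes are A minus B
        (e.g. ``("MPNST", "NF")``). Defaults to the sorted label pair.
    """

    study_id: str
    species: str
    matrix: pd.DataFrame
    groups: pd.Series
    probe_map: pd.Series
    comparison: tuple[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.species not in VALID_SPECIES:
            raise ValueError(f"species must be one of {VALID_SPECIES}, got {self.species!r}")
        if self.matrix.index.has_duplicates:
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise ValueError(f"duplicate probe ID in study {self.study_id!r}: {dup!r}")
        missing = [s for s in self.matrix.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group label in {self.study_id!r}: {missing}")
        self.groups = self.groups.loc[self.matrix.columns]
        levels = sorted(self.groups.unique())
        if len(levels) != 2:
            raise ValueError(
                f"study {self.study_id!r} must have exactly two phenotype groups, got {levels}"
            )
        if self.comparison is None:
            self.comparison = (levels[0], levels[1])
        else:
            self.comparison = tuple(self.comparison)  # type: ignore[assignment]
            if sorted(self.comparison) != levels:
                raise ValueError(
                    f"comparison {self.comparison} does not match group labels {levels}"
                )
        if self.matrix.isna().any().any():
            raise ValueError(f"study {self.study_id!r} matrix contains missing values")

    @property
    def n_probes(self) -> int:
        return self.matrix.shape[0]

    def group_matrices(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Split the matrix into the (A, B) sample blocks of the comparison."""
        a, b = self.comparison  # type: ignore[misc]
        cols_a = self.groups.index[self.groups == a]
        cols_b = self.groups.index[self.groups == b]
        return self.matrix[cols_a], self.matrix[cols_b]

    def swapped(self) -> "ExpressionStudy":
        """Same study with the comparison direction reversed (B vs A)."""
        a, b = self.comparison  # type: ignore[misc]
        return ExpressionStudy(
            study_id=self.study_id,
            species=self.species,
            matrix=self.matrix,
            groups=self.groups,
            probe_map=self.probe_map,
            comparison=(b, a),
        )
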