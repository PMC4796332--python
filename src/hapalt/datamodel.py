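"""Core data types for genotype-panel analysis.

The central objects are :class:`GenotypePanel` (samples x loci derived-allele
dosages plus per-sample metadata), :class:`PopulationTable` (population codes
with residence altitudes) and :class:`Locus` (a biallelic SNP with known
ancestral/derived states).

Dosages count **derived** alleles, not ALT or minor alleles: every downstream
statistic (core-motif calling, derived-allele frequency profiles, selection
inference) is defined on ancestral/derived polarity.  Missing calls are encoded
with the sentinel :data:`MISSING` (-1), which is distinct from any valid dosage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in dosage matrices (int8-compatible).
MISSING: int = -1

SEX_VALUES = ("male", "female", "unknown")

SAMPLE_META_COLUMNS = [
    "sample_id",
    "population_code",
    "reported_sex",
    "genotype_sex",
    "amplified",
    "duplicate_of",
]


class PanelValidationError(ValueError):
    """Raised when a panel, locus set or metadata table violates an invariant."""


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP with polarized allele states.

    Parameters
    ----------
    id : str
        SNP identifier, e.g. ``"rs115321619"``.
    ancestral_allele, derived_allele : str
        Single bases; must differ.
    chrom_pos : int, optional
        1-based reference coordinate (used only for ordering/reporting).
    core_member : bool
        Whether the locus belongs to the core (introgressed-motif) SNP set.
    """

    id: str
    ancestral_allele: str
    derived_allele: str
    chrom_pos: int | None = None
    core_member: bool = False

    def __post_init__(self) -> None:
        if self.ancestral_allele == self.derived_allele:
            raise PanelValidationError(
                f"locus {self.id}: ancestral and derived alleles are both "
                f"{self.ancestral_allele!r}"
            )
        for allele in (self.ancestral_allele, self.derived_allele):
            if len(allele) != 1 or allele not in "ACGT":
                raise PanelValidationError(
                    f"locus {self.id}: allele {allele!r} is not a single base"
                )


@dataclass
class SampleRecord:
    """One genotyped individual: identity, metadata and a dosage vector."""

    sample_id: str
    population_code: str
    reported_sex: str = "unknown"
    genotype_sex: str = "unknown"
    amplified: bool = False
    dosages: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int8))
    duplicate_of: str | None = None

    def __post_init__(self) -> None:
        if self.reported_sex not in SEX_VALUES:
            raise PanelValidationError(
                f"sample {self.sample_id}: reported_sex {self.reported_sex!r}"
            )
        if self.genotype_sex not in SEX_VALUES:
            raise PanelValidationError(
                f"sample {self.sample_id}: genotype_sex {self.genotype_sex!r}"
            )
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise PanelValidationError(
                f"sample {self.sample_id}: invalid dosage values "
                f"{sorted(set(self.dosages[bad].tolist()))}"
            )


class PopulationTable:
    """Populations with country, residence altitude (metres) and sample counts.

    Thin wrapper over a :class:`pandas.DataFrame` with columns
    ``population_code``, ``country``, ``altitude_m``, ``n_samples``.
    """

    COLUMNS = ["population_code", "country", "altitude_m", "n_samples"]

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col in ("population_code", "country"):
            if col not in frame:
                raise PanelValidationError(f"population table missing column {col!r}")
        if "altitude_m" not in frame:
            raise PanelValidationError("population table missing column 'altitude_m'")
        if "n_samples" not in frame:
            frame["n_samples"] = 0
        frame = frame[self.COLUMNS].reset_index(drop=True)
        codes = frame["population_code"]
        if codes.duplicated().any():
            dups = sorted(codes[codes.duplicated()].unique())
            raise PanelValidationError(f"duplicate population codes: {dups}")
        alt = frame["altitude_m"].to_numpy(dtype=float)
        if not np.all(np.isfinite(alt)) or (alt < 0).any():
            raise PanelValidationError("altitudes must be finite and non-negative")
        self.frame = frame

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float] | tuple[str, str, float, int]]
    ) -> "PopulationTable":
        rows = []
        for rec in records:
            code, country, alt = rec[0], rec[1], rec[2]
            n = rec[3] if len(rec) > 3 else 0
            rows.append(
                {"population_code": code, "country": country, "altitude_m": alt,
                 "n_samples": n}
            )
        return cls(pd.DataFrame(rows))

    @property
    def codes(self) -> list[str]:
        return self.frame["population_code"].tolist()

    def altitude(self, code: str) -> float:
        sel = self.frame.loc[self.frame["population_code"] == code, "altitude_m"]
        if sel.empty:
            raise KeyError(code)
        return float(sel.iloc[0])

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PopulationTable) and self.frame.equals(other.frame)


def altitude_class(altitude_m: float) -> str:
    """Classify a residence altitude as ``high``, ``medium`` or ``low``.

    High is strictly above 3000 m, medium is the closed interval
    [2000 m, 3000 m], low is strictly below 2000 m, so the three classes
    partition the non-negative line.
    """
    if not np.isfinite(altitude_m) or altitude_m < 0:
        raise PanelValidationError(f"altitude must be >= 0, got {altitude_m}")
    if altitude_m > 3000:
        return "high"
    if altitude_m >= 2000:
        return "medium"
    return "low"


class GenotypePanel:
    """An ordered locus set, sample metadata and a dosage matrix.

    Attributes
    ----------
    loci : list[Locus]
        Column order of the dosage matrix.
    samples : pandas.DataFrame
        One row per sample, columns :data:`SAMPLE_META_COLUMNS`.
    dosages : numpy.ndarray of int8, shape (n_samples, n_loci)
        Derived-allele counts in {0,1,2}, :data:`MISSING` for no-calls.
    populations : PopulationTable
    """

    def __init__(
        self,
        loci: Sequence[Locus],
        samples: pd.DataFrame,
        dosages: np.ndarray,
        populations: PopulationTable,
    ):
        self.loci = list(loci)
        ids = [loc.id for loc in self.loci]
        if len(set(ids)) != len(ids):
            raise PanelValidationError("locus ids are not unique")
        samples = samples.copy().reset_index(drop=True)
        for col in SAMPLE_META_COLUMNS:
            if col not in samples:
                if col == "amplified":
                    samples[col] = False
                elif col == "duplicate_of":
                    samples[col] = None
                elif col in ("reported_sex", "genotype_sex"):
                    samples[col] = "unknown"
                else:
                    raise PanelValidationError(f"sample table missing column {col!r}")
        self.samples = samples[SAMPLE_META_COLUMNS]
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.shape != (len(samples), len(self.loci)):
            raise PanelValidationError(
                f"dosage matrix shape {dosages.shape} != "
                f"({len(samples)}, {len(self.loci)})"
            )
        bad = ~np.isin(dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise PanelValidationError("dosage matrix contains invalid values")
        self.dosages = dosages
        self.populations = populations
        known = set(populations.codes)
        unknown = sorted(set(self.samples["population_code"]) - known)
        if unknown:
            raise PanelValidationError(
                f"samples reference unknown population codes: {unknown}"
            )

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        loci: Sequence[Locus],
        records: Iterable[SampleRecord],
        populations: PopulationTable,
    ) -> "GenotypePanel":
        records = list(records)
        n_loci = len(loci)
        rows, dosage_rows = [], []
        for rec in records:
            if rec.dosages.shape != (n_loci,):
                raise PanelValidationError(
                    f"sample {rec.sample_id}: dosage vector length "
                    f"{rec.dosages.shape[0]} != panel size {n_loci}"
                )
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "population_code": rec.population_code,
                    "reported_sex": rec.reported_sex,
                    "genotype_sex": rec.genotype_sex,
                    "amplified": rec.amplified,
                    "duplicate_of": rec.duplicate_of,
                }
            )
            dosage_rows.append(rec.dosages)
        samples = pd.DataFrame(rows, columns=SAMPLE_META_COLUMNS)
        dosages = (
            np.vstack(dosage_rows)
            if dosage_rows
            else np.empty((0, n_loci), dtype=np.int8)
        )
        return cls(loci, samples, dosages, populations)

    # -- accessors --------------------------------------------------------

    @property
    def locus_ids(self) -> list[str]:
        return [loc.id for loc in self.loci]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus_id: str) -> int:
        try:
            return self.locus_ids.index(locus_id)
        except ValueError:
            raise KeyError(f"locus {locus_id!r} not in panel") from None

    def sample_records(self) -> Iterable[SampleRecord]:
        for i, row in self.samples.iterrows():
            yield SampleRecord(
                sample_id=row["sample_id"],
                population_code=row["population_code"],
                reported_sex=row["reported_sex"],
                genotype_sex=row["genotype_sex"],
                amplified=bool(row["amplified"]),
                dosages=self.dosages[i],
                duplicate_of=row["duplicate_of"],
            )

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def subset_samples(self, keep: np.ndarray) -> "GenotypePanel":
        """New panel with the boolean/index-selected samples (loci unchanged)."""
        samples = self.samples.loc[keep].reset_index(drop=True)
        return GenotypePanel(self.loci, samples, self.dosages[keep], self.populations)

    def subset_loci(self, keep: np.ndarray) -> "GenotypePanel":
        """New panel with the boolean/index-selected loci (samples unchanged)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            loci = [loc for loc, k in zip(self.loci, keep) if k]
        else:
            loci = [self.loci[i] for i in keep]
        return GenotypePanel(loci, self.samples, self.dosages[:, keep], self.populations)

    def equals(self, other: "GenotypePanel") -> bool:
        return (
            self.loci == other.loci
            and self.samples.equals(other.samples)
            and np.array_equal(self.dosages, other.dosages)
            and self.populations == other.populations
        )
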