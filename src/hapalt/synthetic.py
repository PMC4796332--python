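"""Synthetic genotype-panel generator.

Emulates the statistical structure of a multi-population SNP-panel survey of
an introgressed haplotype region: two divergent haplotype clusters (one
carrying a five-SNP core motif), population core-haplotype frequencies that
rise monotonically with residence altitude, a few mid-panel loci whose
intermediate frequencies do not track altitude (the analogue of the panel
region showing no selection signal in any population), missing calls with a
subset of poorly performing samples, duplicate sample pairs (amplified /
unamplified copies of the same DNA), sex-discordant samples, and a small
per-call genotyping error rate.

The generator works at the haplotype level and returns the true phased
haplotype pair for every sample, so downstream phasing can be scored against
truth.  It deliberately has no coalescent realism — no recombination and no
new mutation — because it imitates the *structure* of the data, not its
history.

Haplotypes are encoded as strings of ``'0'`` (ancestral) / ``'1'`` (derived),
one character per panel locus, in panel column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    GenotypePanel,
    Locus,
    PanelValidationError,
    PopulationTable,
    SAMPLE_META_COLUMNS,
)
from .io import default_panel_loci

# Default core cluster: the common high-altitude haplotype (derived across the
# upstream region including the five-SNP core motif, plus the downstream
# regulatory SNP) and a two-step variant of it.
_CORE_MAIN = "1111111110000001000"
_CORE_MINOR = "1111101110000001000"

# Default background cluster: four haplotypes lacking the core motif, each at
# least six mutational steps from the core cluster (mirroring the observed
# six-SNP separation between the two clusters).
_BACKGROUND = {
    "0000000000000000000": 0.5,
    "0000000001111100000": 0.2,
    "0000011000000000000": 0.2,
    "0000000000000001000": 0.1,
}


def default_core_freq_fn(altitude_m: float) -> float:
    """Logistic altitude -> core-haplotype frequency map.

    Near zero below ~1000 m, ~13% at 2000 m, ~48% at 3000 m and ~75% above
    4000 m, echoing the observed gradient from near-absence in low-altitude
    groups to 60-80% in the highest-altitude populations.
    """
    return float(0.8 / (1.0 + np.exp(-(altitude_m - 2800.0) / 500.0)))


def _default_altitudes(n: int) -> np.ndarray:
    # span the surveyed village altitudes, 86-4550 m
    return np.linspace(86.0, 4550.0, n)


@dataclass
class SimPanelSpec:
    """Parameters of a synthetic panel draw.

    The defaults mirror the study design being emulated: 55 populations of
    ~36 samples each (≈2000 samples), altitudes spanning 86–4550 m, a
    monotone altitude→core-frequency map, ~1% per-call genotyping error
    (duplicate-pair concordance ≈98%), a minority of failed samples with
    heavy missingness, 283 duplicate pairs and 79 sex-discordant samples.
    """

    n_populations: int = 55
    samples_per_pop: int = 36
    altitudes: Sequence[float] | None = None
    core_freq_fn: Callable[[float], float] = field(default=default_core_freq_fn)
    core_haplotypes: dict[str, float] = field(
        default_factory=lambda: {_CORE_MAIN: 0.85, _CORE_MINOR: 0.15}
    )
    background_haplotypes: dict[str, float] = field(
        default_factory=lambda: dict(_BACKGROUND)
    )
    missing_rate: float = 0.02
    failed_sample_rate: float = 0.15
    failed_missing_rate: float = 0.40
    genotype_error_rate: float = 0.01
    duplicate_pairs: int = 283
    sex_discordant: int = 79
    neutral_locus_freqs: dict[int, float] | None = None
    loci: Sequence[Locus] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.altitudes is None:
            self.altitudes = _default_altitudes(self.n_populations)
        self.altitudes = np.asarray(self.altitudes, dtype=float)
        if len(self.altitudes) != self.n_populations:
            raise PanelValidationError(
                "altitudes length must equal n_populations"
            )
        for name, rate in (
            ("missing_rate", self.missing_rate),
            ("failed_sample_rate", self.failed_sample_rate),
            ("failed_missing_rate", self.failed_missing_rate),
            ("genotype_error_rate", self.genotype_error_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise PanelValidationError(f"{name} must be in [0,1], got {rate}")
        if self.loci is None:
            self.loci = default_panel_loci()
        self.loci = list(self.loci)
        n_loci = len(self.loci)
        for hap in list(self.core_haplotypes) + list(self.background_haplotypes):
            if len(hap) != n_loci or set(hap) - {"0", "1"}:
                raise PanelValidationError(f"bad haplotype string {hap!r}")
        if self.neutral_locus_freqs is None:
            # mid-panel polymorphism whose frequency does not track altitude,
            # mirroring the panel region that shows no selection signal in
            # any population; also what anchors the island-model migration
            # rate when the panel is fit for selection
            self.neutral_locus_freqs = {12: 0.35, 16: 0.45, 17: 0.25}
        for j, q in self.neutral_locus_freqs.items():
            if not 0 <= j < n_loci:
                raise PanelValidationError(f"neutral locus index {j} out of range")
            if not 0.0 <= q <= 1.0:
                raise PanelValidationError(
                    f"neutral locus frequency {q} outside [0,1]"
                )


def _normalize(weights: dict[str, float]) -> tuple[list[str], np.ndarray]:
    haps = sorted(weights)
    w = np.array([weights[h] for h in haps], dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise PanelValidationError("haplotype weights must be non-negative, sum > 0")
    return haps, w / w.sum()


def simulate_panel(spec: SimPanelSpec) -> tuple[GenotypePanel, pd.DataFrame]:
    """Draw a synthetic panel; returns ``(panel, truth)``.

    ``truth`` has one row per sample: ``sample_id``, ``population_code``,
    ``hap1``, ``hap2`` (binary haplotype strings, the true phase).  Dosages in
    the returned panel are the sum of the two drawn haplotypes' derived
    alleles, after genotyping error and missingness injection; truth is
    error-free.
    """
    rng = np.random.default_rng(spec.seed)
    loci = list(spec.loci)
    n_loci = len(loci)
    core_haps, core_w = _normalize(spec.core_haplotypes)
    bg_haps, bg_w = _normalize(spec.background_haplotypes)
    hap_arrays = {
        h: np.frombuffer(h.encode(), dtype=np.uint8) - ord("0")
        for h in core_haps + bg_haps
    }

    pop_codes = [f"P{k:02d}" for k in range(spec.n_populations)]
    pop_rows = [
        {
            "population_code": code,
            "country": "synthetic",
            "altitude_m": float(alt),
            "n_samples": spec.samples_per_pop,
        }
        for code, alt in zip(pop_codes, spec.altitudes)
    ]
    populations = PopulationTable(pd.DataFrame(pop_rows))

    meta_rows: list[dict] = []
    true_rows: list[np.ndarray] = []
    truth_rows: list[dict] = []

    neutral = sorted(spec.neutral_locus_freqs.items())

    def draw_chromosome(p_core: float) -> np.ndarray:
        if rng.random() < p_core:
            hap = core_haps[rng.choice(len(core_haps), p=core_w)]
        else:
            hap = bg_haps[rng.choice(len(bg_haps), p=bg_w)]
        bits = hap_arrays[hap].copy()
        for j, q in neutral:
            bits[j] = rng.random() < q
        return bits

    for code, alt in zip(pop_codes, spec.altitudes):
        p_core = spec.core_freq_fn(float(alt))
        if not 0.0 <= p_core <= 1.0:
            raise PanelValidationError(
                f"core_freq_fn({alt}) = {p_core} outside [0,1]"
            )
        for i in range(spec.samples_per_pop):
            c1 = draw_chromosome(p_core)
            c2 = draw_chromosome(p_core)
            sid = f"{code}_{i:04d}"
            sex = "male" if rng.random() < 0.5 else "female"
            meta_rows.append(
                {
                    "sample_id": sid,
                    "population_code": code,
                    "reported_sex": sex,
                    "genotype_sex": sex,
                    "amplified": True,
                    "duplicate_of": None,
                }
            )
            true_rows.append(c1 + c2)
            truth_rows.append(
                {"sample_id": sid, "population_code": code,
                 "hap1": "".join("01"[b] for b in c1),
                 "hap2": "".join("01"[b] for b in c2)}
            )

    n_base = len(meta_rows)

    # sex-discordant samples: genotype sex disagrees with the reported sex
    if spec.sex_discordant > n_base:
        raise PanelValidationError("sex_discordant exceeds sample count")
    discordant = rng.choice(n_base, size=spec.sex_discordant, replace=False)
    for i in discordant:
        rep = meta_rows[i]["reported_sex"]
        meta_rows[i]["genotype_sex"] = "female" if rep == "male" else "male"

    # duplicate pairs: an unamplified second aliquot of the same DNA
    if spec.duplicate_pairs > n_base:
        raise PanelValidationError("duplicate_pairs exceeds sample count")
    dup_src = rng.choice(n_base, size=spec.duplicate_pairs, replace=False)
    for i in dup_src:
        src = meta_rows[i]
        sid = src["sample_id"] + "_dup"
        meta_rows.append(
            {
                "sample_id": sid,
                "population_code": src["population_code"],
                "reported_sex": src["reported_sex"],
                "genotype_sex": src["genotype_sex"],
                "amplified": False,
                "duplicate_of": src["sample_id"],
            }
        )
        true_rows.append(true_rows[i].copy())
        t = truth_rows[i]
        truth_rows.append(
            {"sample_id": sid, "population_code": t["population_code"],
             "hap1": t["hap1"], "hap2": t["hap2"]}
        )

    dosages = np.vstack(true_rows).astype(np.int8)
    n_total = dosages.shape[0]

    # per-call genotyping error: replace with a uniform draw from the other
    # two dosage values
    if spec.genotype_error_rate > 0:
        err = rng.random(dosages.shape) < spec.genotype_error_rate
        shift = rng.integers(1, 3, size=dosages.shape)
        dosages = np.where(err, (dosages + shift) % 3, dosages).astype(np.int8)

    # missingness: failed samples have a much higher no-call rate
    failed = rng.random(n_total) < spec.failed_sample_rate
    rates = np.where(failed, spec.failed_missing_rate, spec.missing_rate)
    miss = rng.random(dosages.shape) < rates[:, None]
    dosages[miss] = MISSING

    samples = pd.DataFrame(meta_rows, columns=SAMPLE_META_COLUMNS)
    panel = GenotypePanel(loci, samples, dosages, populations)
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "population_code",
                                              "hap1", "hap2"])
    return panel, truth


def write_truth_haplotypes(truth: pd.DataFrame, path: str | Path) -> None:
    """Write truth phase as a two-row-per-sample TSV (sample_id, which, haplotype)."""
    with open(path, "w") as fh:
        fh.write("sample_id\tchromosome\thaplotype\n")
        for _, row in truth.iterrows():
            fh.write(f"{row['sample_id']}\t1\t{row['hap1']}\n")
            fh.write(f"{row['sample_id']}\t2\t{row['hap2']}\n")


def read_truth_haplotypes(path: str | Path) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t", dtype=str)
    wide = long.pivot(index="sample_id", columns="chromosome", values="haplotype")
    out = wide.rename(columns={"1": "hap1", "2": "hap2"}).reset_index()
    out.columns.name = None
    return out[["sample_id", "hap1", "hap2"]]
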