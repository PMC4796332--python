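import numpy as np
import pandas as pd
import pytest

from hapalt.datamodel import (
    GenotypePanel,
    Locus,
    PopulationTable,
    SampleRecord,
)


def make_loci(n: int, core: int = 0) -> list[Locus]:
    """n synthetic loci; the first `core` are core-motif members."""
    bases = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    return [
        Locus(
            id=f"L{j:02d}",
            ancestral_allele=bases[j % 4][0],
            derived_allele=bases[j % 4][1],
            chrom_pos=1000 + j,
            core_member=j < core,
        )
        for j in range(n)
    ]


def make_panel(
    dosages,
    pop_codes=None,
    altitudes=None,
    loci=None,
    reported_sex=None,
    genotype_sex=None,
    core=0,
):
    """Build a small GenotypePanel from a dosage matrix."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    loci = loci or make_loci(m, core=core)
    pop_codes = pop_codes or ["AAA"] * n
    uniq = sorted(set(pop_codes))
    altitudes = altitudes or {c: 1000.0 for c in uniq}
    pops = PopulationTable.from_records(
        [(c, "testland", altitudes[c]) for c in uniq]
    )
    records = []
    for i in range(n):
        records.append(
            SampleRecord(
                sample_id=f"S{i:03d}",
                population_code=pop_codes[i],
                reported_sex=(reported_sex or ["unknown"] * n)[i],
                genotype_sex=(genotype_sex or ["unknown"] * n)[i],
                dosages=dosages[i],
            )
        )
    return GenotypePanel.from_records(loci, records, pops)


@pytest.fixture
def two_cluster_spec():
    """A small, clean two-cluster synthetic spec (no errors, no missing)."""
    from hapalt.synthetic import SimPanelSpec

    return SimPanelSpec(
        n_populations=6,
        samples_per_pop=40,
        missing_rate=0.0,
        failed_sample_rate=0.0,
        genotype_error_rate=0.0,
        duplicate_pairs=0,
        sex_discordant=0,
        neutral_locus_freqs={},
        seed=11,
    )
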