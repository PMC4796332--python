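"""Readers and writers for panel configuration, genotype tables and VCF.

Tabular genotype dialect
------------------------
Tab-separated, one sample per row.  Header columns, in order:
``sample_id``, ``population_code``, ``reported_sex``, then optionally
``genotype_sex``, ``amplified``, ``duplicate_of``, then one column per locus id.
Genotype cells hold the derived-allele dosage ``0``/``1``/``2`` or ``.`` for a
missing call.

Population tables are TSV with columns ``population_code``, ``country``,
``altitude_m`` (and optionally ``n_samples``).

The VCF reader handles a v4.2 GT-only subset and converts genotypes to
derived-allele dosages using the panel's derived allele — not the ALT allele —
so a record whose REF is the derived base yields dosage 2 for GT 0/0.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    MISSING,
    GenotypePanel,
    Locus,
    PanelValidationError,
    PopulationTable,
    SAMPLE_META_COLUMNS,
)

MISSING_SYMBOL = "."
_META_OPTIONAL = ["genotype_sex", "amplified", "duplicate_of"]


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# panel configuration


def load_panel_config(path: str | Path | None = None) -> tuple[list[Locus], dict]:
    """Load a locus-panel YAML; ``None`` loads the bundled default panel.

    Returns the ordered locus list and the raw config dict (which may carry
    auxiliary keys such as named region boundaries).
    """
    if path is None:
        ref = importlib.resources.files("hapalt.data") / "default_panel.yaml"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    loci = [
        Locus(
            id=entry["id"],
            ancestral_allele=entry["ancestral"],
            derived_allele=entry["derived"],
            chrom_pos=entry.get("pos"),
            core_member=bool(entry.get("core", False)),
        )
        for entry in cfg["loci"]
    ]
    ids = [loc.id for loc in loci]
    if len(set(ids)) != len(ids):
        raise PanelValidationError("panel config has duplicate locus ids")
    return loci, cfg


def default_panel_loci() -> list[Locus]:
    return load_panel_config(None)[0]


# ---------------------------------------------------------------------------
# population tables


def read_population_table(path: str | Path) -> PopulationTable:
    frame = pd.read_csv(path, sep="\t", dtype={"population_code": str})
    return PopulationTable(frame)


def write_population_table(pops: PopulationTable, path: str | Path) -> None:
    pops.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tabular genotypes


def read_genotypes(
    path: str | Path,
    populations: PopulationTable,
    loci: Sequence[Locus] | None = None,
    fmt: str = "tabular",
    sample_metadata: pd.DataFrame | None = None,
) -> GenotypePanel:
    """Read a genotype file into a validated :class:`GenotypePanel`.

    ``fmt`` selects the dialect: ``"tabular"`` (the package's TSV dialect) or
    ``"vcf"``.  For VCF input, per-sample population codes must be supplied
    via ``sample_metadata`` (columns ``sample_id``, ``population_code`` and
    optionally the sex/amplification columns).
    """
    if loci is None:
        loci = default_panel_loci()
    if fmt == "tabular":
        return _read_tabular(Path(path), populations, list(loci))
    if fmt == "vcf":
        return _read_vcf(Path(path), populations, list(loci), sample_metadata)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_tabular(
    path: Path, populations: PopulationTable, loci: list[Locus]
) -> GenotypePanel:
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise ParseError(f"{path}: line 1: empty header")
        header = header_line.split("\t")
        if header[:3] != ["sample_id", "population_code", "reported_sex"]:
            raise ParseError(
                f"{path}: line 1: header must start with sample_id, "
                f"population_code, reported_sex"
            )
        meta_cols = ["sample_id", "population_code", "reported_sex"]
        idx = 3
        for col in _META_OPTIONAL:
            if idx < len(header) and header[idx] == col:
                meta_cols.append(col)
                idx += 1
        locus_cols = header[idx:]
        expected = [loc.id for loc in loci]
        if locus_cols != expected:
            raise ParseError(
                f"{path}: line 1: locus columns {locus_cols} do not match the "
                f"panel {expected}"
            )
        n_meta = len(meta_cols)
        rows, dosage_rows = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} columns, "
                    f"got {len(fields)}"
                )
            meta = dict(zip(meta_cols, fields[:n_meta]))
            if "amplified" in meta:
                meta["amplified"] = meta["amplified"].lower() in ("1", "true", "yes")
            if meta.get("duplicate_of", "") in ("", MISSING_SYMBOL):
                meta["duplicate_of"] = None
            rows.append(meta)
            dosages = np.empty(len(loci), dtype=np.int8)
            for j, cell in enumerate(fields[n_meta:]):
                if cell == MISSING_SYMBOL:
                    dosages[j] = MISSING
                elif cell in ("0", "1", "2"):
                    dosages[j] = int(cell)
                else:
                    raise ParseError(
                        f"{path}: line {lineno}: invalid dosage {cell!r} at "
                        f"locus {loci[j].id}"
                    )
            dosage_rows.append(dosages)
    samples = pd.DataFrame(rows)
    for col in SAMPLE_META_COLUMNS:
        if col not in samples:
            samples[col] = (
                False if col == "amplified"
                else None if col == "duplicate_of"
                else "unknown"
            )
    dosage_mat = (
        np.vstack(dosage_rows) if dosage_rows else np.empty((0, len(loci)), np.int8)
    )
    return GenotypePanel(loci, samples, dosage_mat, populations)


def write_genotypes(panel: GenotypePanel, path: str | Path) -> None:
    """Write a panel in the tabular dialect with all metadata columns."""
    header = (
        ["sample_id", "population_code", "reported_sex"]
        + _META_OPTIONAL
        + panel.locus_ids
    )
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i, row in panel.samples.iterrows():
            meta = [
                row["sample_id"],
                row["population_code"],
                row["reported_sex"],
                row["genotype_sex"],
                "1" if row["amplified"] else "0",
                row["duplicate_of"] if row["duplicate_of"] else MISSING_SYMBOL,
            ]
            cells = [
                MISSING_SYMBOL if d == MISSING else str(int(d))
                for d in panel.dosages[i]
            ]
            fh.write("\t".join(meta + cells) + "\n")


# ---------------------------------------------------------------------------
# VCF


def _read_vcf(
    path: Path,
    populations: PopulationTable,
    loci: list[Locus],
    sample_metadata: pd.DataFrame | None,
) -> GenotypePanel:
    import pysam

    if sample_metadata is None:
        raise PanelValidationError(
            "VCF input requires sample_metadata with population codes"
        )
    by_id = {loc.id: j for j, loc in enumerate(loci)}
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        dosages = np.full((len(sample_names), len(loci)), MISSING, dtype=np.int8)
        seen: set[str] = set()
        for rec in vcf:
            if rec.id not in by_id:
                continue
            j = by_id[rec.id]
            locus = loci[j]
            alleles = [rec.ref] + list(rec.alts or [])
            derived_idx = {
                k for k, a in enumerate(alleles) if a == locus.derived_allele
            }
            valid = {locus.ancestral_allele, locus.derived_allele}
            bad = [a for a in alleles if a not in valid]
            if bad:
                raise PanelValidationError(
                    f"{path}: locus {locus.id}: allele(s) {bad} match neither "
                    f"ancestral {locus.ancestral_allele} nor derived "
                    f"{locus.derived_allele}"
                )
            seen.add(rec.id)
            for i, name in enumerate(sample_names):
                gt = rec.samples[name].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                dosages[i, j] = sum(1 for a in gt if a in derived_idx)
    meta = sample_metadata.set_index("sample_id")
    missing_samples = [s for s in sample_names if s not in meta.index]
    if missing_samples:
        raise PanelValidationError(
            f"no sample metadata for VCF samples: {missing_samples}"
        )
    rows = []
    for name in sample_names:
        rec = meta.loc[name]
        rows.append(
            {
                "sample_id": name,
                "population_code": rec["population_code"],
                "reported_sex": rec.get("reported_sex", "unknown"),
                "genotype_sex": rec.get("genotype_sex", "unknown"),
                "amplified": bool(rec.get("amplified", False)),
                "duplicate_of": rec.get("duplicate_of", None),
            }
        )
    samples = pd.DataFrame(rows, columns=SAMPLE_META_COLUMNS)
    return GenotypePanel(loci, samples, dosages, populations)
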