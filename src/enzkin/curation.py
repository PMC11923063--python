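"""Curation of raw enzyme kinetic measurement tables.

Raw tables (BRENDA/SABIO-RK-style exports) carry one row per measurement:
UniProt accession, enzyme sequence, substrate name, SMILES, parameter type
(kcat or Km), value and unit.  Curation drops rows that cannot be used
(multiple accessions, missing SMILES or sequence), normalizes units to the
canonical scales (kcat in s⁻¹, Km in mM), collapses repeated measurements of
one enzyme-substrate pair — keeping the maximum kcat and the minimum Km —
and emits log10-scale labels together with a per-pair label-noise estimate
(the population std of the log10 replicate values).

The catalytic-efficiency dataset is the key intersection of the curated kcat
and Km datasets; its label is log10(kcat) − log10(Km) exactly.
"""

from __future__ import annotations

import json
import math
import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "KineticRecord", "Entry", "CuratedDataset", "DEFAULT_UNIT_CONVERSIONS",
    "load_records", "filter_units", "deduplicate", "label_noise",
    "intersect_ratio",
]

#: Unit → multiplicative factor to the canonical unit, per parameter.
#: Canonical units: kcat in s⁻¹, Km in mM.  Units absent from this table are
#: treated as ambiguous and the rows carrying them are removed.
DEFAULT_UNIT_CONVERSIONS: dict[str, dict[str, float]] = {
    "kcat": {
        "s^(-1)": 1.0, "s^-1": 1.0, "s-1": 1.0, "1/s": 1.0, "/s": 1.0,
        "min^(-1)": 1 / 60, "min^-1": 1 / 60, "min-1": 1 / 60, "1/min": 1 / 60,
        "h^(-1)": 1 / 3600, "h^-1": 1 / 3600, "1/h": 1 / 3600,
    },
    "km": {
        "mM": 1.0, "mm": 1.0,
        "M": 1000.0,
        "uM": 1e-3, "µM": 1e-3, "μM": 1e-3,
        "nM": 1e-6,
    },
}

REQUIRED_COLUMNS = ("enzyme_id", "substrate_name", "param", "value", "unit")
OPTIONAL_COLUMNS = ("sequence", "smiles", "organism", "ec_number", "enzyme_type")


@dataclass(frozen=True)
class KineticRecord:
    """One enzyme-substrate kinetic measurement as read from a raw table."""

    enzyme_id: str
    sequence: str
    substrate_name: str
    smiles: str
    param: str  # "kcat" | "km"
    value_raw: float
    unit: str
    organism: str = ""
    ec_number: str = ""
    enzyme_type: str = "wild_type"  # "wild_type" | "mutant"

    @property
    def key(self) -> tuple[str, str]:
        return (self.sequence, self.smiles)


@dataclass
class Entry:
    """One curated (sequence, smiles) entry with its log10 label."""

    sequence: str
    smiles: str
    label: float
    noise_std: float | None = None
    enzyme_id: str = ""
    enzyme_type: str = "wild_type"
    substrate_name: str = ""
    # parent labels, populated for catalytic-efficiency (ratio) entries only
    kcat_label: float | None = None
    km_label: float | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.sequence, self.smiles)


@dataclass
class CuratedDataset:
    """Curated dataset for one parameter: kcat, km, or ratio (kcat/Km)."""

    param: str
    entries: dict[tuple[str, str], Entry] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def keys(self):
        return self.entries.keys()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sequence": e.sequence, "smiles": e.smiles, "label": e.label,
                "noise_std": e.noise_std, "enzyme_id": e.enzyme_id,
                "enzyme_type": e.enzyme_type,
                "substrate_name": e.substrate_name,
                "kcat_label": e.kcat_label, "km_label": e.km_label,
            }
            for e in self.entries.values()
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, param: str) -> "CuratedDataset":
        df = pd.read_csv(path, sep="\t")
        ds = cls(param=param)
        for row in df.itertuples(index=False):
            e = Entry(
                sequence=row.sequence, smiles=row.smiles,
                label=float(row.label),
                noise_std=None if pd.isna(getattr(row, "noise_std", None))
                else float(row.noise_std),
                enzyme_id=str(getattr(row, "enzyme_id", "") or ""),
                enzyme_type=str(getattr(row, "enzyme_type", "wild_type")
                                or "wild_type"),
                substrate_name=str(getattr(row, "substrate_name", "") or ""),
                kcat_label=None if pd.isna(getattr(row, "kcat_label", None))
                else float(row.kcat_label),
                km_label=None if pd.isna(getattr(row, "km_label", None))
                else float(row.km_label),
            )
            ds.entries[e.key] = e
        return ds


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) \
        or (isinstance(value, str) and value.strip() == "")


def load_records(
    table_path: str | Path,
    fasta_path: str | Path | None = None,
) -> tuple[list[KineticRecord], dict[str, int]]:
    """Read a raw kinetic table into records, dropping unusable rows.

    Parameters
    ----------
    table_path
        CSV or TSV file with columns ``enzyme_id, substrate_name, param,
        value, unit`` and optionally ``sequence, smiles, organism, ec_number,
        enzyme_type``.  The delimiter is inferred from the extension
        (``.tsv``/``.tab`` → tab, otherwise comma).
    fasta_path
        Optional FASTA file supplying sequences by ``enzyme_id``; used to
        fill rows whose ``sequence`` column is empty.

    Returns
    -------
    (records, skip_report)
        ``skip_report`` counts rows dropped for (a) multiple UniProt IDs,
        (b) missing SMILES, (c) missing sequence.
    """
    table_path = Path(table_path)
    sep = "\t" if table_path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(table_path, sep=sep, dtype=str, keep_default_na=False,
                         na_values=[""])
    except OSError as err:
        raise OSError(f"cannot read kinetic table {table_path}: {err}") from err

    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(
                f"kinetic table {table_path} is missing required column "
                f"'{col}' (found: {list(df.columns)})"
            )

    seq_by_id: dict[str, str] = {}
    if fasta_path is not None:
        from Bio import SeqIO

        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            seq_by_id[rec.id] = str(rec.seq).upper()

    records: list[KineticRecord] = []
    report = {"multiple_uniprot_ids": 0, "missing_smiles": 0,
              "missing_sequence": 0}
    for row in df.itertuples(index=False):
        enzyme_id = str(row.enzyme_id).strip()
        # rows listing several accessions cannot be mapped to one sequence
        if any(sep_ in enzyme_id for sep_ in (";", ",", " ")):
            report["multiple_uniprot_ids"] += 1
            continue
        smiles = getattr(row, "smiles", None)
        if _is_missing(smiles):
            report["missing_smiles"] += 1
            continue
        sequence = getattr(row, "sequence", None)
        if _is_missing(sequence):
            sequence = seq_by_id.get(enzyme_id)
        if _is_missing(sequence):
            report["missing_sequence"] += 1
            continue
        records.append(
            KineticRecord(
                enzyme_id=enzyme_id,
                sequence=str(sequence).upper(),
                substrate_name=str(row.substrate_name),
                smiles=str(smiles),
                param=str(row.param).lower(),
                value_raw=float(row.value),
                unit="" if _is_missing(row.unit) else str(row.unit).strip(),
                organism=str(getattr(row, "organism", "") or ""),
                ec_number=str(getattr(row, "ec_number", "") or ""),
                enzyme_type=str(getattr(row, "enzyme_type", "") or
                                "wild_type"),
            )
        )
    return records, report


def filter_units(
    records: Iterable[KineticRecord],
    allowed_units_per_param: Mapping[str, Mapping[str, float]] | None = None,
) -> list[KineticRecord]:
    """Remove records with ambiguous units; convert the rest to canonical units.

    A unit is ambiguous when it is absent from the conversion table for the
    record's parameter (this includes the empty string).  Retained records
    have ``value_raw`` rescaled to s⁻¹ (kcat) or mM (Km) and their unit label
    rewritten to the canonical one.
    """
    table = allowed_units_per_param or DEFAULT_UNIT_CONVERSIONS
    canonical = {"kcat": "s^(-1)", "km": "mM"}
    out: list[KineticRecord] = []
    for rec in records:
        conv = table.get(rec.param, {})
        if rec.unit not in conv:
            continue
        out.append(replace(rec, value_raw=rec.value_raw * conv[rec.unit],
                           unit=canonical.get(rec.param, rec.unit)))
    return out


def deduplicate(records: Iterable[KineticRecord], param: str) -> CuratedDataset:
    """Collapse repeated measurements of one (sequence, smiles) pair.

    kcat keeps the maximum value, Km keeps the minimum; the label is the
    log10 of the retained value.  Non-positive values are rejected and
    counted in ``dataset.meta['rejected_nonpositive']``.  The operation is
    idempotent and order-independent.
    """
    if param not in ("kcat", "km"):
        raise ValueError(f"param must be 'kcat' or 'km', got {param!r}")
    keep_max = param == "kcat"
    best: dict[tuple[str, str], KineticRecord] = {}
    rejected = 0
    for rec in records:
        if rec.param != param:
            raise ValueError(
                f"record with param {rec.param!r} passed to deduplicate "
                f"for {param!r}"
            )
        if rec.value_raw <= 0:
            rejected += 1
            continue
        cur = best.get(rec.key)
        better = cur is not None and (
            rec.value_raw > cur.value_raw if keep_max
            else rec.value_raw < cur.value_raw
        )
        if cur is None or better:
            best[rec.key] = rec
    ds = CuratedDataset(param=param,
                        meta={"rejected_nonpositive": rejected})
    for key, rec in best.items():
        ds.entries[key] = Entry(
            sequence=rec.sequence, smiles=rec.smiles,
            label=math.log10(rec.value_raw),
            enzyme_id=rec.enzyme_id, enzyme_type=rec.enzyme_type,
            substrate_name=rec.substrate_name,
        )
    return ds


def label_noise(
    records: Iterable[KineticRecord] | None, param: str
) -> dict[tuple[str, str], float]:
    """Per-pair label noise: population std of the log10 replicate values.

    Computed on the raw (pre-deduplication) records; pairs with a single
    measurement are omitted.  Non-positive values are ignored (they cannot
    be log-transformed and are rejected downstream anyway).
    """
    groups: dict[tuple[str, str], list[float]] = {}
    for rec in records or ():
        if rec.param != param or rec.value_raw <= 0:
            continue
        groups.setdefault(rec.key, []).append(math.log10(rec.value_raw))
    return {
        key: statistics.pstdev(vals)
        for key, vals in groups.items()
        if len(vals) > 1
    }


def attach_noise(
    dataset: CuratedDataset, noise: Mapping[tuple[str, str], float]
) -> CuratedDataset:
    """Annotate entries in place with their label-noise std, where present."""
    for key, std in noise.items():
        if key in dataset.entries:
            dataset.entries[key].noise_std = std
    return dataset


def intersect_ratio(
    kcat_ds: CuratedDataset, km_ds: CuratedDataset
) -> CuratedDataset:
    """Catalytic-efficiency dataset: pairs with both a kcat and a Km entry.

    The label is log10(kcat) − log10(Km) of the parent entries, exactly.
    """
    ds = CuratedDataset(param="ratio")
    for key in kcat_ds.keys() & km_ds.keys():
        kc, km = kcat_ds.entries[key], km_ds.entries[key]
        ds.entries[key] = Entry(
            sequence=kc.sequence, smiles=kc.smiles,
            label=kc.label - km.label,
            enzyme_id=kc.enzyme_id, enzyme_type=kc.enzyme_type,
            substrate_name=kc.substrate_name,
            kcat_label=kc.label, km_label=km.label,
        )
    return ds


def curate_pipeline(
    table_path: str | Path,
    fasta_path: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, CuratedDataset]:
    """Full curation: load → unit filter → noise → dedup → ratio intersect.

    Returns the three curated datasets keyed by ``kcat``, ``km``, ``ratio``;
    optionally writes them (plus a JSON skip report) under ``out_dir``.
    """
    records, report = load_records(table_path, fasta_path)
    records = filter_units(records)
    datasets: dict[str, CuratedDataset] = {}
    for param in ("kcat", "km"):
        recs = [r for r in records if r.param == param]
        ds = deduplicate(recs, param)
        attach_noise(ds, label_noise(recs, param))
        datasets[param] = ds
    datasets["ratio"] = intersect_ratio(datasets["kcat"], datasets["km"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for param, ds in datasets.items():
            ds.to_tsv(out / f"{param}.tsv")
        (out / "skip_report.json").write_text(json.dumps(report, indent=2))
    return datasets
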