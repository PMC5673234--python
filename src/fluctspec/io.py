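"""Readers and writers for the pipeline's plain-text formats.

All tabular files are tab-delimited UTF-8 with a header row and '.' decimal
separator.  Upper-bound rates are serialized as a numeric column plus an
``is_upper_bound`` flag so files stay machine-readable; pretty-printers
render the "<23" style.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import pandas as pd
from Bio import SeqIO

from .compare import ContingencyTable
from .rates import Culture, CultureSet, RateEstimate
from .spectrum import MutationRecord, MutationSpectrum, RatePartition

__all__ = [
    "read_culture_tsv",
    "write_culture_tsv",
    "read_reference_fasta",
    "read_mutations_tsv",
    "read_spectrum_tsv",
    "write_spectrum_tsv",
    "read_contingency_tsv",
    "write_rate_estimate",
    "write_partition_tsv",
    "write_config_json",
]

CULTURE_COLUMNS = [
    "culture_id",
    "selective_count",
    "selective_dilution",
    "permissive_count",
    "permissive_dilution",
    "verified_silenced_count",
]


def read_culture_tsv(path: str | Path, genotype: str = "", locus: str = "") -> CultureSet:
    """Load fluctuation-assay plate counts, validating row by row."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CULTURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    cultures = []
    for i, row in df.iterrows():
        try:
            cultures.append(
                Culture(
                    selective_count=int(row["selective_count"]),
                    selective_dilution=float(row["selective_dilution"]),
                    permissive_count=int(row["permissive_count"]),
                    permissive_dilution=float(row["permissive_dilution"]),
                    verified_silenced_count=int(row["verified_silenced_count"]),
                )
            )
        except ValueError as e:
            raise ValueError(f"{path}: row {i + 1}: {e}") from e
    return CultureSet(genotype=genotype, locus=locus, cultures=cultures)


def write_culture_tsv(cs: CultureSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "culture_id": [f"c{i + 1}" for i in range(len(cs))],
            "selective_count": [c.selective_count for c in cs.cultures],
            "selective_dilution": [c.selective_dilution for c in cs.cultures],
            "permissive_count": [c.permissive_count for c in cs.cultures],
            "permissive_dilution": [c.permissive_dilution for c in cs.cultures],
            "verified_silenced_count": [
                c.verified_silenced_count for c in cs.cultures
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_reference_fasta(path: str | Path) -> str:
    """Single-record FASTA -> uppercase sequence (ACGTN alphabet)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"{path}: expected exactly one FASTA record, found {len(records)}"
        )
    seq = str(records[0].seq).upper()
    if not seq:
        raise ValueError(f"{path}: empty sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"{path}: invalid characters {sorted(bad)}")
    return seq


def read_mutations_tsv(path: str | Path) -> list[MutationRecord]:
    """Mutation calls: isolate_id, position, ref_allele, alt_allele."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    needed = ["isolate_id", "position", "ref_allele", "alt_allele"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                MutationRecord(
                    isolate_id=row["isolate_id"],
                    position=int(row["position"]),
                    ref_allele=row["ref_allele"],
                    alt_allele=row["alt_allele"],
                )
            )
        except ValueError as e:
            raise ValueError(f"{path}: row {i + 1}: {e}") from e
    return out


def read_spectrum_tsv(path: str | Path, genotype: str = "") -> MutationSpectrum:
    df = pd.read_csv(path, sep="\t")
    if not {"category", "count"} <= set(df.columns):
        raise ValueError(f"{path}: need columns category, count")
    return MutationSpectrum(
        genotype=genotype or Path(path).stem,
        counts={str(r["category"]): int(r["count"]) for _, r in df.iterrows()},
    )


def write_spectrum_tsv(spectrum: MutationSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"category": list(spectrum.counts), "count": list(spectrum.counts.values())}
    ).to_csv(path, sep="\t", index=False)


def read_contingency_tsv(path: str | Path) -> ContingencyTable:
    """Rows = categories, columns = genotypes; first column is the row label."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ContingencyTable.from_frame(df)


def write_rate_estimate(est: RateEstimate, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(est), fh, indent=2)
        fh.write("\n")


def write_partition_tsv(
    partition: RatePartition, path: str | Path
) -> None:
    rows = []
    for cat, rate in partition.rates.items():
        rows.append(
            {
                "category": cat,
                "rate": rate,
                "relative_rate": partition.relative.get(cat, float("nan")),
                "is_upper_bound": partition.bound_flags[cat],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_config_json(config: Any, path: str | Path) -> None:
    payload = (
        dataclasses.asdict(config) if dataclasses.is_dataclass(config) else config
    )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
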