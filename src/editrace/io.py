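"""Text-format interfaces: FASTA/FASTQ, sidecar TSVs, allele tables.

All inter-stage tables are TSV with a ``# config=<sha256>`` comment line
so every output records the parameter snapshot that produced it.  Floats
are written with six significant digits for diffable, bit-stable output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .core import (
    Amplicon,
    DataError,
    DonorSpec,
    EditAllele,
    SampleTable,
    parse_signature,
)
from .reads import BarcodeTable, MergedRead, ReadPair

__all__ = [
    "config_hash",
    "read_amplicons",
    "write_amplicons",
    "read_donors",
    "read_barcode_table",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "write_fastq_single",
    "read_fastq_single",
    "write_sample_tables",
    "read_sample_tables",
    "write_table",
    "read_table",
]


def config_hash(config: object) -> str:
    """Stable short hash of any JSON-serializable parameter snapshot."""
    try:
        payload = json.dumps(config, sort_keys=True, default=str)
    except TypeError:
        payload = repr(config)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, config: object = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config={config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# Amplicons and donors


def read_amplicons(fasta_path: str | Path, sidecar_path: str | Path) -> dict[str, Amplicon]:
    """Load amplicons from FASTA plus a sidecar TSV.

    Sidecar columns: ``id``, ``protospacer``, ``pam_start``, ``strand``.
    """
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    sidecar = read_table(sidecar_path)
    required = {"id", "protospacer", "pam_start", "strand"}
    if missing := required - set(sidecar.columns):
        raise DataError(f"amplicon sidecar is missing columns: {sorted(missing)}")
    amplicons = {}
    for row in sidecar.itertuples():
        if row.id not in sequences:
            raise DataError(f"amplicon {row.id!r} absent from the FASTA")
        amplicons[row.id] = Amplicon(
            id=row.id,
            reference_sequence=sequences[row.id],
            protospacer=str(row.protospacer).upper(),
            pam_start=int(row.pam_start),
            strand=str(row.strand),
        )
    return amplicons


def write_amplicons(
    amplicons: Iterable[Amplicon], fasta_path: str | Path, sidecar_path: str | Path
) -> None:
    amplicons = list(amplicons)
    fasta_path = Path(fasta_path)
    fasta_path.parent.mkdir(parents=True, exist_ok=True)
    with open(fasta_path, "w") as fh:
        for a in amplicons:
            fh.write(f">{a.id}\n{a.reference_sequence}\n")
    df = pd.DataFrame(
        {
            "id": [a.id for a in amplicons],
            "protospacer": [a.protospacer for a in amplicons],
            "pam_start": [a.pam_start for a in amplicons],
            "strand": [a.strand for a in amplicons],
        }
    )
    write_table(df, sidecar_path)


def read_donors(path: str | Path, amplicons: Mapping[str, Amplicon]) -> dict[str, DonorSpec]:
    """Donor TSV: ``amplicon_id``, ``insert_sequence``, ``arm_length``."""
    df = read_table(path)
    required = {"amplicon_id", "insert_sequence"}
    if missing := required - set(df.columns):
        raise DataError(f"donor table is missing columns: {sorted(missing)}")
    donors = {}
    for row in df.itertuples():
        if row.amplicon_id not in amplicons:
            raise DataError(f"donor references unknown amplicon {row.amplicon_id!r}")
        arm = int(getattr(row, "arm_length", 600))
        donors[row.amplicon_id] = DonorSpec(
            insert_sequence=str(row.insert_sequence).upper(),
            insertion_point=amplicons[row.amplicon_id].cut_site,
            homology_arm_length=arm,
        )
    return donors


def read_barcode_table(path: str | Path, max_mismatch: int = 1) -> BarcodeTable:
    """Barcode TSV: ``sample_id``, ``barcode``, ``amplicon_id``."""
    df = read_table(path)
    required = {"sample_id", "barcode", "amplicon_id"}
    if missing := required - set(df.columns):
        raise DataError(f"barcode table is missing columns: {sorted(missing)}")
    return BarcodeTable(
        samples=tuple(
            (str(r.sample_id), str(r.barcode).upper(), str(r.amplicon_id))
            for r in df.itertuples()
        ),
        max_mismatch=max_mismatch,
    )


# ---------------------------------------------------------------------------
# FASTQ


def _phred33(quals: Iterable[int]) -> str:
    return "".join(chr(min(q, 60) + 33) for q in quals)


def write_fastq_pairs(
    pairs: Iterable[ReadPair], r1_path: str | Path, r2_path: str | Path, prefix: str = "read"
) -> None:
    r1_path, r2_path = Path(r1_path), Path(r2_path)
    r1_path.parent.mkdir(parents=True, exist_ok=True)
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for i, pair in enumerate(pairs):
            f1.write(f"@{prefix}_{i}/1\n{pair.r1_seq}\n+\n{_phred33(pair.r1_qual)}\n")
            f2.write(f"@{prefix}_{i}/2\n{pair.r2_seq}\n+\n{_phred33(pair.r2_qual)}\n")


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    r1 = list(SeqIO.parse(str(r1_path), "fastq"))
    r2 = list(SeqIO.parse(str(r2_path), "fastq"))
    if len(r1) != len(r2):
        raise DataError("R1/R2 FASTQ files have different read counts")
    return [
        ReadPair(
            str(a.seq),
            str(b.seq),
            tuple(a.letter_annotations["phred_quality"]),
            tuple(b.letter_annotations["phred_quality"]),
        )
        for a, b in zip(r1, r2)
    ]


def write_fastq_single(
    reads: Iterable[MergedRead], path: str | Path, prefix: str = "merged"
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{read.seq}\n+\n{_phred33(read.qual)}\n")


def read_fastq_single(path: str | Path) -> list[MergedRead]:
    return [
        MergedRead(str(rec.seq), tuple(rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


# ---------------------------------------------------------------------------
# Allele tables


def sample_tables_to_frame(samples: Iterable[SampleTable]) -> pd.DataFrame:
    rows = []
    for s in samples:
        for a in s.alleles:
            rows.append(
                {
                    "amplicon_id": s.amplicon_id,
                    "condition": s.condition,
                    "timepoint_h": s.timepoint_h,
                    "total_reads": s.total_reads,
                    "unaligned_reads": s.unaligned_reads,
                    "signature": a.signature,
                    "count": a.read_count,
                    "frequency": a.frequency,
                    "repair_class": a.repair_class,
                    "category": a.category,
                }
            )
        if not s.alleles:
            rows.append(
                {
                    "amplicon_id": s.amplicon_id,
                    "condition": s.condition,
                    "timepoint_h": s.timepoint_h,
                    "total_reads": s.total_reads,
                    "unaligned_reads": s.unaligned_reads,
                    "signature": "WT",
                    "count": 0,
                    "frequency": 0.0,
                    "repair_class": "unedited",
                    "category": "",
                }
            )
    return pd.DataFrame(rows)


def write_sample_tables(
    samples: Iterable[SampleTable], path: str | Path, config: object = None
) -> None:
    write_table(sample_tables_to_frame(samples), path, config=config)


def read_sample_tables(path: str | Path) -> list[SampleTable]:
    df = read_table(path)
    samples = []
    keys = ["amplicon_id", "condition", "timepoint_h"]
    for (amplicon_id, condition, timepoint), group in df.groupby(keys, sort=False):
        alleles = [
            EditAllele(
                ops=parse_signature(row["signature"]),
                read_count=int(row["count"]),
                frequency=float(row["frequency"]),
                repair_class=str(row.get("repair_class", "unclassified")),
                category="" if pd.isna(row.get("category", "")) else str(row.get("category")),
            )
            for _, row in group.iterrows()
            if row["signature"] != "WT"
        ]
        samples.append(
            SampleTable(
                amplicon_id=str(amplicon_id),
                condition=str(condition),
                timepoint_h=float(timepoint),
                total_reads=int(group["total_reads"].iloc[0]),
                alleles=alleles,
                unaligned_reads=int(group["unaligned_reads"].iloc[0]),
            )
        )
    return samples
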