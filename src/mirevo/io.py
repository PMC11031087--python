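"""Readers and writers for the plain-text formats the pipeline exchanges.

All intervals are 0-based half-open internally; 1-based conversions happen
only at the VCF boundary.  Malformed lines raise with file/line diagnostics
rather than being skipped silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .conservation import ConservationTrack
from .de import CountMatrix
from .scan import TargetSite


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: str = "0"
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError("BED interval must satisfy 0 <= start < end")


def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id, in file order."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path) -> list[BedRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            records.append(
                BedRecord(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    name=fields[3] if len(fields) > 3 else ".",
                    score=fields[4] if len(fields) > 4 else "0",
                    strand=fields[5] if len(fields) > 5 else ".",
                )
            )
    return records


def write_bed(path, records: Iterable[BedRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\t{rec.score}\t{rec.strand}\n"
            )


def sites_to_bed(sites: Iterable[TargetSite], chrom_of=None) -> list[BedRecord]:
    """BED6 records for target sites; name encodes mirna|class|tier."""
    out = []
    for s in sites:
        chrom = chrom_of(s.transcript) if chrom_of else s.transcript
        out.append(
            BedRecord(
                chrom=chrom,
                start=s.start,
                end=s.end,
                name=f"{s.mirna}|{s.site_class}|{s.predictor_tier}",
                score=str(s.wobble_count),
                strand="+",
            )
        )
    return out


def read_bedgraph(path, semantics: str = "phylop") -> ConservationTrack:
    """Four-column bedGraph into a conservation track.

    Overlapping intervals are rejected with a file/line diagnostic.
    """
    track = ConservationTrack(semantics=semantics)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: bedGraph line needs 4 fields")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph fields") from exc
            try:
                track.add_value(fields[0], start, end, value)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return track


def write_bedgraph(path, track: ConservationTrack) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            for start, values in track._segments[chrom]:
                for offset, v in enumerate(values):
                    fh.write(f"{chrom}\t{start + offset}\t{start + offset + 1}\t{v:.6g}\n")


def read_vcf_minimal(path, daf_field: str = "DAF") -> pd.DataFrame:
    """Minimal VCF reader: position, alleles, and a DAF INFO field only.

    Positions are converted to 0-based.  A record without the DAF field (or
    any malformed line) raises with a line diagnostic.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: VCF record has fewer than 8 fields")
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            try:
                pos0 = int(pos) - 1
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer POS") from exc
            info = dict(
                kv.split("=", 1) if "=" in kv else (kv, "")
                for kv in fields[7].split(";")
                if kv
            )
            if daf_field not in info:
                raise ValueError(f"{path}:{lineno}: INFO field {daf_field!r} absent")
            try:
                daf = float(info[daf_field])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric {daf_field}") from exc
            rows.append(
                {"chrom": chrom, "pos": pos0, "id": vid, "ref": ref, "alt": alt, "daf": daf}
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt", "daf"])


def read_counts_tsv(path) -> CountMatrix:
    """Counts TSV with gene rows and ``LINE_rN`` sample columns."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    meta_rows = []
    for sample in counts.columns:
        if "_r" not in sample:
            raise ValueError(
                f"{path}: sample column {sample!r} does not follow the LINE_rN convention"
            )
        line, rep = sample.rsplit("_r", 1)
        meta_rows.append({"sample": sample, "line": line, "replicate": int(rep)})
    samples = pd.DataFrame(meta_rows).set_index("sample")
    return CountMatrix(counts=counts.astype(int), samples=samples)


def write_counts_tsv(path, cm: CountMatrix) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene")


def read_de_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    required = {"gene", "log2fc", "pvalue", "fdr", "line"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: DE table missing columns {sorted(missing)}")
    return frame


def read_assays_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    required = {"assay_id", "type", "genotype_A_count", "genotype_B_count", "ratio_A", "ratio_B"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: assay table missing columns {sorted(missing)}")
    return frame


def lift_sites_to_genome(sites: Iterable[TargetSite], utr) -> list[BedRecord]:
    """Map UTR-coordinate sites onto the UTR's genomic blocks.

    Sites spanning a block boundary split into one BED record per block;
    minus-strand blocks are mirrored so genomic start < end always.  This is
    the inverse of per-base score mapping.
    """
    if not utr.genomic_intervals:
        raise ValueError(f"UTR {utr.transcript} has no genomic intervals")
    blocks = []
    offset = 0
    for chrom, start, end, strand in utr.genomic_intervals:
        blocks.append((offset, offset + (end - start), chrom, start, end, strand))
        offset += end - start
    utr_len = offset
    out = []
    for site in sites:
        if site.end > utr_len:
            raise ValueError(f"site [{site.start}, {site.end}) beyond UTR length {utr_len}")
        for b_off, b_end_off, chrom, g_start, g_end, strand in blocks:
            lo, hi = max(site.start, b_off), min(site.end, b_end_off)
            if lo >= hi:
                continue
            if strand == "-":
                # UTR position p in this block maps to genomic g_end - 1 - (p - b_off)
                gs, ge = g_end - (hi - b_off), g_end - (lo - b_off)
            else:
                gs, ge = g_start + (lo - b_off), g_start + (hi - b_off)
            out.append(
                BedRecord(
                    chrom=chrom,
                    start=gs,
                    end=ge,
                    name=f"{site.mirna}|{site.site_class}|{site.predictor_tier}",
                    score=str(site.wobble_count),
                    strand=strand,
                )
            )
    return out
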