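"""Readers and writers for the pipeline's on-disk formats.

FASTA/FASTQ go through Biopython; tables (MLPA peaks, aCGH probes, cohort,
cluster reports) are tab-separated files handled with pandas.  Repeat tracks
are read and written both as BED6+1 (0-based half-open, the extra column
carrying the repeat class) and as RepeatMasker ``.out`` tables (1-based
inclusive, ``C`` for minus strand).  Rearrangement calls are emitted as TSV
and as VCF 4.2 symbolic structural-variant records.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import ReferenceLocus, RearrangementCall, RepeatElement

# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(path: str, records: Iterable[tuple[str, str]]) -> None:
    """Write ``(name, sequence)`` pairs as FASTA."""
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, path, "fasta")


def read_fasta(path: str) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]


def write_locus_fasta(path: str, locus: ReferenceLocus) -> None:
    """FASTA with the genomic offset recorded in the header (``name:offset``)."""
    write_fasta(path, [(f"{locus.name}:{locus.offset}", locus.sequence)])


def read_locus_fasta(path: str) -> ReferenceLocus:
    name, seq = read_fasta(path)[0]
    if ":" in name:
        base, _, off = name.rpartition(":")
        try:
            return ReferenceLocus(base, int(off), seq)
        except ValueError:
            pass
    return ReferenceLocus(name, 1, seq)


def write_fastq(path: str, reads: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    """Write ``(read_id, sequence)`` pairs as FASTQ with a constant quality line."""
    records = []
    for rid, seq in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [ord(quality_char) - 33] * len(seq)
        records.append(rec)
    SeqIO.write(records, path, "fastq")


def read_reads(path: str) -> list[tuple[str, str]]:
    """Read FASTQ or FASTA reads, sniffing the format from the extension."""
    fmt = "fastq" if os.path.splitext(path)[1].lower() in (".fastq", ".fq") else "fasta"
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, fmt)]


# ---------------------------------------------------------------------------
# Repeat tracks: BED6+1 and RepeatMasker .out

_CLASS_DEFAULT = {
    "Alu": "SINE",
    "L1": "LINE",
    "L2": "LINE",
    "LINE": "LINE",
    "LTR": "LTR",
    "MER": "DNA",
    "DNA": "DNA",
}


def _guess_class(family: str) -> str:
    for prefix, cls in _CLASS_DEFAULT.items():
        if family.startswith(prefix):
            return cls
    return "SINE"


def write_repeats_bed(path: str, repeats: Sequence[RepeatElement], chrom: str = "locus") -> None:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(
                f"{chrom}\t{r.start - 1}\t{r.end}\t{r.family}\t0\t{r.strand}\t{r.class_}\n"
            )


def read_repeats_bed(path: str) -> list[RepeatElement]:
    repeats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            family = f[3] if len(f) > 3 else "repeat"
            strand = f[5] if len(f) > 5 else "+"
            cls = f[6] if len(f) > 6 else _guess_class(family)
            repeats.append(
                RepeatElement(family=family, start=int(f[1]) + 1, end=int(f[2]),
                              strand=strand, class_=cls)
            )
    return sorted(repeats, key=lambda r: (r.start, r.end))


_RM_HEADER = (
    "   SW  perc perc perc  query     position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)   repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def write_repeats_rmout(
    path: str, repeats: Sequence[RepeatElement], locus: ReferenceLocus
) -> None:
    """RepeatMasker ``.out`` dialect (1-based inclusive, ``C`` = minus strand)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, r in enumerate(repeats, start=1):
            strand = "+" if r.strand == "+" else "C"
            qleft = locus.end - r.end
            rlen = len(r)
            fh.write(
                f"{1000:>5} {0.0:4.1f} {0.0:4.1f} {0.0:4.1f}  {locus.name:<9} "
                f"{r.start:>8} {r.end:>7} ({qleft})  {strand} {r.family:<14} "
                f"{r.class_ + '/' + r.family:<18} {1:>5} {rlen:>4} (0) {i:>4}\n"
            )


def read_repeats_rmout(path: str) -> list[RepeatElement]:
    repeats = []
    with open(path) as fh:
        for line in fh:
            f = line.split()
            if len(f) < 14 or not f[0].isdigit():
                continue  # header / blank lines
            strand = "+" if f[8] == "+" else "-"
            family = f[9]
            cls = f[10].split("/")[0]
            if cls not in ("SINE", "LINE", "LTR", "DNA"):
                cls = _guess_class(family)
            repeats.append(
                RepeatElement(family=family, start=int(f[5]), end=int(f[6]),
                              strand=strand, class_=cls)
            )
    return sorted(repeats, key=lambda r: (r.start, r.end))


# ---------------------------------------------------------------------------
# Tables

MLPA_COLUMNS = ["sample_id", "reaction", "probe", "exon", "peak_area", "is_reference"]
CGH_COLUMNS = ["chrom", "position", "log2_ratio"]
COHORT_COLUMNS = [
    "family_id", "individual_id", "criteria", "mutation_class",
    "carrier", "affected", "tumors", "pathogenic",
]


def write_table(path: str, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_mlpa_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MLPA_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"MLPA table missing columns: {sorted(missing)}")
    if "is_reference" not in df.columns:
        df["is_reference"] = False
    return df


def read_cgh_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"position", "log2_ratio"} - set(df.columns)
    if missing:
        raise ValueError(f"aCGH table missing columns: {sorted(missing)}")
    return df


def read_cohort_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    for col in ("carrier", "affected", "pathogenic"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin(("true", "1", "yes"))
    return df


# ---------------------------------------------------------------------------
# Rearrangement calls: TSV and VCF 4.2 symbolic records


def calls_to_frame(calls: Sequence[RearrangementCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        j = c.junction
        rows.append(
            {
                "event_type": c.event_type,
                "start": c.start,
                "end": c.end,
                "size": c.size,
                "mechanism": c.mechanism,
                "microhomology_len": j.microhomology_len if j else "",
                "microhomology_seq": j.microhomology_seq if j else "",
                "inserted_seq": j.inserted_seq if j else "",
                "repeat5": c.repeat5.family if c.repeat5 else "-",
                "repeat3": c.repeat3.family if c.repeat3 else "-",
                "nomenclature_report_style": c.nomenclature_report_style,
                "nomenclature_hgvs": c.nomenclature_hgvs,
                "pathogenic": c.pathogenic_flag,
                "pathogenic_rationale": c.pathogenic_rationale,
            }
        )
    return pd.DataFrame(rows)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=rearrangemap
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=DUP:TANDEM,Description="Tandem duplication">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">
##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Length of breakpoint microhomology">
##INFO=<ID=HOMSEQ,Number=1,Type=String,Description="Sequence of breakpoint microhomology">
##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Untemplated insertion at the junction">
##INFO=<ID=MECHANISM,Number=1,Type=String,Description="Proposed mechanism (NAHR/NHEJ/unclassified)">
"""


def write_calls_vcf(
    path: str,
    calls: Sequence[RearrangementCall],
    locus: ReferenceLocus,
    chrom: str = "2",
) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(f"##contig=<ID={chrom},length={locus.end}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(calls, start=1):
            pos = c.start - 1  # base before the event, VCF SV convention
            ref = locus.base(pos) if locus.contains(pos) else "N"
            if c.event_type == "deletion":
                alt, svtype, svlen = "<DEL>", "DEL", -c.size
            else:
                alt, svtype, svlen = "<DUP:TANDEM>", "DUP", c.size
            info = [f"SVTYPE={svtype}", f"END={c.end}", f"SVLEN={svlen}"]
            if c.junction is not None:
                info.append(f"HOMLEN={c.junction.microhomology_len}")
                if c.junction.microhomology_seq:
                    info.append(f"HOMSEQ={c.junction.microhomology_seq}")
                if c.junction.inserted_seq:
                    info.append(f"INSSEQ={c.junction.inserted_seq}")
            info.append(f"MECHANISM={c.mechanism}")
            fh.write(
                f"{chrom}\t{pos}\tsv{i}\t{ref}\t{alt}\t.\tPASS\t{';'.join(info)}\n"
            )
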