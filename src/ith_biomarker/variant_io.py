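"""Readers and writers for the standard formats the pipeline touches.

MAF (TCGA dialect), VCF v4.2+ with per-sample AD, SEG-like TSV and a
clinical TSV are normalized into the internal data model.  All coordinates
become 1-based inclusive.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .model import ClinicalRecord, CopyNumberSegment, Effect, VariantCall

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A file does not follow the expected dialect."""


# TCGA MAF Variant_Classification -> internal effect enumeration
MAF_CLASSIFICATION_MAP = {
    "Missense_Mutation": Effect.MISSENSE,
    "Nonsense_Mutation": Effect.NONSENSE,
    "Nonstop_Mutation": Effect.NONSENSE,
    "Frame_Shift_Del": Effect.FRAMESHIFT,
    "Frame_Shift_Ins": Effect.FRAMESHIFT,
    "Splice_Site": Effect.SPLICE,
    "Splice_Region": Effect.SPLICE,
    "In_Frame_Del": Effect.INFRAME_INDEL,
    "In_Frame_Ins": Effect.INFRAME_INDEL,
    "Translation_Start_Site": Effect.MISSENSE,
    "Silent": Effect.SYNONYMOUS,
    "3'UTR": Effect.NONCODING,
    "5'UTR": Effect.NONCODING,
    "3'Flank": Effect.NONCODING,
    "5'Flank": Effect.NONCODING,
    "Intron": Effect.NONCODING,
    "IGR": Effect.NONCODING,
    "RNA": Effect.NONCODING,
    "lincRNA": Effect.NONCODING,
}

_EFFECT_TO_MAF = {
    Effect.MISSENSE: "Missense_Mutation",
    Effect.NONSENSE: "Nonsense_Mutation",
    Effect.FRAMESHIFT: "Frame_Shift_Del",
    Effect.SPLICE: "Splice_Site",
    Effect.INFRAME_INDEL: "In_Frame_Del",
    Effect.SYNONYMOUS: "Silent",
    Effect.NONCODING: "Intron",
}

MAF_REQUIRED_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
    "t_ref_count",
    "t_alt_count",
]


def _coerce_effect(value) -> Effect:
    """Accept either the internal enum value or a MAF classification string."""
    s = str(value)
    if s in MAF_CLASSIFICATION_MAP:
        return MAF_CLASSIFICATION_MAP[s]
    try:
        return Effect(s)
    except ValueError:
        raise FormatError(f"unknown variant classification {s!r}") from None


def read_maf(path: PathLike, drop_countless: bool = True) -> list[VariantCall]:
    """Read a TCGA-dialect MAF into VariantCall records.

    Rows with missing read counts are dropped with a warning when
    ``drop_countless`` is True (default), otherwise they raise.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"MAF is missing required column(s): {', '.join(missing)}")

    calls: list[VariantCall] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        raw_ref, raw_alt = row["t_ref_count"], row["t_alt_count"]
        if pd.isna(raw_ref) or pd.isna(raw_alt):
            if drop_countless:
                warnings.warn(f"MAF line {line_no}: missing read counts, row dropped")
                continue
            raise FormatError(f"MAF line {line_no}: missing read counts")
        try:
            ref_count, alt_count = int(raw_ref), int(raw_alt)
        except ValueError:
            raise FormatError(
                f"MAF line {line_no}: non-integer read counts "
                f"({raw_ref!r}, {raw_alt!r})"
            ) from None
        calls.append(
            VariantCall(
                chrom=str(row["Chromosome"]),
                pos=int(row["Start_Position"]),
                ref=str(row["Reference_Allele"]),
                alt=str(row["Tumor_Seq_Allele2"]),
                ref_count=ref_count,
                alt_count=alt_count,
                gene="" if pd.isna(row["Hugo_Symbol"]) else str(row["Hugo_Symbol"]),
                effect=_coerce_effect(row["Variant_Classification"]),
                sample_id=str(row["Tumor_Sample_Barcode"]),
            )
        )
    return calls


def write_maf(calls: Iterable[VariantCall], path: PathLike) -> None:
    """Write VariantCalls as a minimal TCGA-dialect MAF (round-trips read_maf)."""
    rows = [
        {
            "Hugo_Symbol": c.gene,
            "Chromosome": c.chrom,
            "Start_Position": c.pos,
            "Reference_Allele": c.ref,
            "Tumor_Seq_Allele2": c.alt,
            "Variant_Classification": _EFFECT_TO_MAF[c.effect],
            "Tumor_Sample_Barcode": c.sample_id,
            "t_ref_count": c.ref_count,
            "t_alt_count": c.alt_count,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=MAF_REQUIRED_COLUMNS).to_csv(path, sep="\t", index=False)


def read_vcf(path: PathLike, sample: Optional[str] = None) -> list[VariantCall]:
    """Read a VCF with per-sample AD depths; one VariantCall per ALT allele.

    Multi-allelic records are split: AD[0] is the reference depth, AD[i]
    the depth of the i-th ALT.
    """
    from cyvcf2 import VCF  # deferred: htslib import is relatively slow

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare OSError on malformed input
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    if not samples:
        raise FormatError("VCF has no sample columns; allelic depths are required")
    if sample is None:
        sample_idx, sample = 0, samples[0]
    else:
        if sample not in samples:
            raise FormatError(f"sample {sample!r} not in VCF (has {samples})")
        sample_idx = samples.index(sample)

    calls: list[VariantCall] = []
    for rec_no, rec in enumerate(vcf, start=1):
        try:
            ad = rec.format("AD")
        except KeyError:  # AD absent from the FORMAT header lines
            ad = None
        if ad is None:
            raise FormatError(
                f"VCF record {rec_no} ({rec.CHROM}:{rec.POS}) lacks the AD FORMAT "
                "field; supply per-sample allelic depths"
            )
        depths = [int(x) for x in ad[sample_idx]]
        if len(depths) != 1 + len(rec.ALT):
            raise FormatError(
                f"VCF record {rec_no}: AD has {len(depths)} values for "
                f"{len(rec.ALT)} ALT allele(s)"
            )
        for alt_i, alt in enumerate(rec.ALT, start=1):
            calls.append(
                VariantCall(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    ref_count=max(depths[0], 0),
                    alt_count=max(depths[alt_i], 0),
                    gene="",
                    effect=Effect.MISSENSE,
                    sample_id=sample,
                )
            )
    return calls


SEG_COLUMNS = ["chrom", "start", "end", "major_cn", "minor_cn", "sample_id"]


def read_segments(path: PathLike) -> list[CopyNumberSegment]:
    """Read allele-specific copy-number segments from a SEG-like TSV.

    Overlapping segments within one sample are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"segment file missing column(s): {', '.join(missing)}")
    segments = [
        CopyNumberSegment(
            chrom=str(r["chrom"]),
            start=int(r["start"]),
            end=int(r["end"]),
            major_cn=int(r["major_cn"]),
            minor_cn=int(r["minor_cn"]),
            sample_id=str(r["sample_id"]),
        )
        for _, r in df.iterrows()
    ]
    _check_no_overlap(segments)
    return segments


def _check_no_overlap(segments: Sequence[CopyNumberSegment]) -> None:
    by_key: dict[tuple[str, str], list[CopyNumberSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    for group in by_key.values():
        group.sort(key=lambda s: s.start)
        for prev, cur in zip(group, group[1:]):
            if cur.start <= prev.end:
                raise FormatError(
                    f"overlapping segments for sample {prev.sample_id!r} on "
                    f"{prev.chrom}: {prev.start}-{prev.end} and {cur.start}-{cur.end}"
                )


def write_segments(segments: Iterable[CopyNumberSegment], path: PathLike) -> None:
    rows = [
        {
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "major_cn": s.major_cn,
            "minor_cn": s.minor_cn,
            "sample_id": s.sample_id,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


CLINICAL_COLUMNS = ["patient_id", "dcb", "orr", "pfs_days", "pfs_event", "purity"]


def read_clinical(path: PathLike) -> list[ClinicalRecord]:
    """Read the clinical outcome TSV; duplicate patient ids are rejected."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"clinical file missing column(s): {', '.join(missing)}")
    dupes = df["patient_id"][df["patient_id"].duplicated()].unique()
    if len(dupes):
        raise FormatError(f"duplicate patient_id(s): {', '.join(map(str, dupes))}")
    return [
        ClinicalRecord(
            patient_id=str(r["patient_id"]),
            dcb=_parse_bool(r["dcb"]),
            orr=_parse_bool(r["orr"]),
            pfs_days=float(r["pfs_days"]),
            pfs_event=_parse_bool(r["pfs_event"]),
            purity=float(r["purity"]),
        )
        for _, r in df.iterrows()
    ]


def _parse_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise FormatError(f"cannot parse boolean value {value!r}")


def write_clinical(records: Iterable[ClinicalRecord], path: PathLike) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "dcb": int(r.dcb),
            "orr": int(r.orr),
            "pfs_days": r.pfs_days,
            "pfs_event": int(r.pfs_event),
            "purity": r.purity,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


DEFAULT_SEGMENT = CopyNumberSegment(chrom="*", start=1, end=1, major_cn=1, minor_cn=1)


class SegmentIndex:
    """Sorted per-(sample, chrom) interval index for copy-number lookup."""

    def __init__(self, segments: Sequence[CopyNumberSegment]):
        _check_no_overlap(segments)
        self._by_key: dict[tuple[str, str], list[CopyNumberSegment]] = {}
        for seg in segments:
            self._by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
        for group in self._by_key.values():
            group.sort(key=lambda s: s.start)

    def lookup(
        self,
        variant: VariantCall,
        default: CopyNumberSegment = DEFAULT_SEGMENT,
    ) -> CopyNumberSegment:
        import bisect

        group = self._by_key.get((variant.sample_id, variant.chrom))
        if group is None:
            group = self._by_key.get(("", variant.chrom), [])
        starts = [s.start for s in group]
        i = bisect.bisect_right(starts, variant.pos) - 1
        if i >= 0 and group[i].start <= variant.pos <= group[i].end:
            return group[i]
        return default


def lookup_cn(
    variant: VariantCall,
    segments: Union[SegmentIndex, Sequence[CopyNumberSegment]],
    default: CopyNumberSegment = DEFAULT_SEGMENT,
) -> CopyNumberSegment:
    """Return the segment containing the variant, or ``default`` (diploid 1/1).

    Intervals are 1-based inclusive on both ends.
    """
    if not isinstance(segments, SegmentIndex):
        segments = SegmentIndex(segments)
    return segments.lookup(variant, default=default)
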