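"""Call-set containers and readers/writers.

The package compares variant calls between replicate sequencing experiments
of the same genomic DNA.  Three kinds of input are handled here:

* per-replicate SNV call sets, read from VCF (e.g. VarScan2 output) or from
  a per-position consensus table;
* per-position consensus genotype tables covering the whole sequenced
  region, in a simple documented TSV dialect (the upstream caller's native
  consensus format is proprietary; this dialect is a synthetic stand-in);
* auxiliary tracks: capture-target BED intervals and windowed GC content.

Coordinates are 1-based fully closed throughout, matching VCF; BED input
(0-based half-open) is converted on read.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: IUPAC ambiguity codes for heterozygous genotypes.
IUPAC_HET = {
    "R": ("A", "G"), "Y": ("C", "T"), "S": ("C", "G"),
    "W": ("A", "T"), "K": ("G", "T"), "M": ("A", "C"),
}
HET_TO_IUPAC = {alleles: code for code, alleles in IUPAC_HET.items()}

BASES = ("A", "C", "G", "T")

ANNOTATION_CLASSES = (
    "exonic", "intronic", "UTR3", "UTR5", "intergenic",
    "upstream", "downstream", "exonic_splicing", "splicing", "ncRNA",
)

EXONIC_CLASSES = ("synonymous", "nonsynonymous", "stopgain", "stoploss", "unknown")
MA_CATEGORIES = ("high", "medium", "low", "neutral", "unknown")

#: Continuous per-call factors used throughout the analysis.
FACTOR_NAMES = ("coverage", "vac", "vaf", "vaq", "pvalue")


class ConsensusSchemaError(ValueError):
    """Consensus table is missing required columns."""


class ConsensusRowError(ValueError):
    """A consensus row violates an invariant (reported with line number)."""


def genotype_from_call(call: str, ref: str) -> tuple[str, str]:
    """Decode a consensus call symbol into an unordered allele pair.

    A plain base is a homozygous genotype; an IUPAC two-base code is
    heterozygous.  ``N`` is ambiguous and has no genotype.
    """
    call = call.upper()
    if call in BASES:
        return (call, call)
    if call in IUPAC_HET:
        return IUPAC_HET[call]
    raise ValueError(f"not a genotype symbol: {call!r}")


def call_from_genotype(genotype: tuple[str, str]) -> str:
    a, b = sorted(genotype)
    if a == b:
        return a
    return HET_TO_IUPAC[(a, b)]


@dataclass(frozen=True)
class VariantCall:
    """One called SNV at a position, with its genotype and factor values.

    ``genotype`` is an unordered allele pair (stored sorted); a homozygous
    call repeats the allele.  ``variant_allele`` is the most abundant
    non-reference allele; ``vac`` counts the reads supporting it, ``vaf``
    its frequency among all reads, ``vaq`` the mean per-read quality of
    those reads (0-35 scale), and ``pvalue`` the caller's SNV-call p-value.
    Factor fields may be ``None`` when the source lacks them.
    """

    chrom: str
    pos: int
    ref: str
    genotype: tuple[str, str]
    variant_allele: str
    coverage: Optional[float] = None
    vac: Optional[float] = None
    vaf: Optional[float] = None
    vaq: Optional[float] = None
    pvalue: Optional[float] = None
    annotation: Optional[str] = None
    exonic_class: Optional[str] = None
    ma_category: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "genotype", tuple(sorted(self.genotype)))
        if self.ref not in BASES:
            raise ValueError(f"ref must be one of {BASES}, got {self.ref!r}")
        if self.variant_allele == self.ref:
            raise ValueError("variant_allele equals ref")
        if not any(a != self.ref for a in self.genotype):
            raise ValueError("genotype contains no non-reference allele")
        if self.vac is not None and self.coverage is not None and self.vac > self.coverage:
            raise ValueError(f"vac {self.vac} > coverage {self.coverage} at {self.chrom}:{self.pos}")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")
        if self.pvalue is not None and not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"pvalue out of [0,1]: {self.pvalue}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def factor(self, name: str) -> Optional[float]:
        """Continuous factor value by name (coverage/vac/vaf/vaq/pvalue)."""
        if name not in FACTOR_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    @property
    def substitution(self) -> str:
        """Substitution category, e.g. ``"A>G"``."""
        return f"{self.ref}>{self.variant_allele}"


@dataclass
class CallSet:
    """All calls from one sequencing replicate.

    ``variants`` maps (chrom, pos) to :class:`VariantCall`.  ``consensus``
    optionally holds the per-position consensus table for the whole
    sequenced region as a DataFrame indexed by (chrom, pos) with columns
    ref, call, coverage, vac, vaf, vaq, pvalue.
    """

    sample_id: str
    replicate_id: str
    variants: dict[tuple[str, int], VariantCall] = field(default_factory=dict)
    consensus: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if self.consensus is not None and not isinstance(self.consensus.index, pd.MultiIndex):
            raise ValueError("consensus must be indexed by (chrom, pos)")

    def __len__(self) -> int:
        return len(self.variants)

    def add(self, v: VariantCall) -> None:
        if v.key in self.variants:
            raise ValueError(f"duplicate variant at {v.key}")
        self.variants[v.key] = v

    def factor_at(self, key: tuple[str, int], name: str) -> Optional[float]:
        """Factor value at a position: the variant record's value if the
        position was called, else the consensus-table value there."""
        v = self.variants.get(key)
        if v is not None:
            val = v.factor(name)
            if val is not None:
                return val
        if self.consensus is not None and key in self.consensus.index:
            val = self.consensus.loc[key, name]
            if pd.notna(val):
                return float(val)
        return None

    def restrict_to(self, keys: Iterable[tuple[str, int]]) -> "CallSet":
        keep = set(keys)
        return CallSet(
            sample_id=self.sample_id,
            replicate_id=self.replicate_id,
            variants={k: v for k, v in self.variants.items() if k in keep},
            consensus=self.consensus,
        )


@dataclass
class ReplicateSet:
    """Two or three replicate call sets from the same source sample."""

    sample_id: str
    replicates: list[CallSet]
    batch_ids: Optional[list[str]] = None

    def __post_init__(self):
        if not 2 <= len(self.replicates) <= 3:
            raise ValueError("a ReplicateSet holds 2 or 3 replicates")
        for cs in self.replicates:
            if cs.sample_id != self.sample_id:
                raise ValueError(
                    f"replicate sample_id {cs.sample_id!r} != {self.sample_id!r}")
        if self.batch_ids is not None and len(self.batch_ids) != len(self.replicates):
            raise ValueError("batch_ids length mismatch")

    def pairs(self) -> list[tuple[CallSet, CallSet]]:
        reps = self.replicates
        return [(reps[i], reps[j]) for i in range(len(reps)) for j in range(i + 1, len(reps))]


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path, sample_id: Optional[str] = None,
             replicate_id: Optional[str] = None) -> CallSet:
    """Read biallelic SNV records from a VCF into a CallSet.

    Field mapping: FORMAT/DP (else INFO/DP) -> coverage; FORMAT/AD -> vac
    (a VarScan-style scalar alt depth, or the alt entry of a standard
    ref,alt tuple); FORMAT/FREQ (percent string) or FORMAT/AF or INFO/AF
    -> vaf, else vac/coverage; FORMAT/ABQ -> vaq; FORMAT/PVAL or INFO/PVAL
    -> pvalue.  Missing fields stay absent rather than zero.  Indel and
    multi-allelic records are skipped and counted in the log.
    """
    import pysam

    path = str(path)
    cs = CallSet(sample_id=sample_id or Path(path).stem,
                 replicate_id=replicate_id or Path(path).stem)
    n_skipped = 0
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1 \
                    or rec.ref not in BASES or alts[0] not in BASES:
                n_skipped += 1
                continue
            alt = alts[0]
            smp = rec.samples[0] if len(rec.samples) else None

            def fmt(key):
                if smp is not None and key in smp and smp[key] is not None:
                    return smp[key]
                return None

            coverage = fmt("DP")
            if coverage is None:
                coverage = rec.info.get("DP")
            ad = fmt("AD")
            if isinstance(ad, (tuple, list)):
                vac = ad[1] if len(ad) > 1 else ad[0]
            else:
                vac = ad
            vaf = None
            freq = fmt("FREQ")
            if freq is not None:
                vaf = float(str(freq).rstrip("%")) / 100.0
            else:
                af = fmt("AF")
                if af is None:
                    af = rec.info.get("AF")
                if af is not None:
                    vaf = float(af[0] if isinstance(af, (tuple, list)) else af)
            if vaf is None and vac is not None and coverage:
                vaf = float(vac) / float(coverage)
            vaq = fmt("ABQ")
            pval = fmt("PVAL")
            if pval is None:
                pval = rec.info.get("PVAL")

            genotype = (rec.ref, alt)
            gt = fmt("GT")
            if gt is not None and None not in gt:
                alleles = [rec.ref] + list(alts)
                genotype = tuple(alleles[i] for i in gt[:2])
                if not any(a != rec.ref for a in genotype):
                    n_skipped += 1  # reference-genotype record, not a variant
                    continue
            cs.add(VariantCall(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, genotype=genotype,
                variant_allele=alt,
                coverage=None if coverage is None else float(coverage),
                vac=None if vac is None else float(vac),
                vaf=vaf,
                vaq=None if vaq is None else float(vaq),
                pvalue=None if pval is None else float(pval),
            ))
    if n_skipped:
        logger.info("read_vcf(%s): skipped %d non-SNV/reference records", path, n_skipped)
    return cs


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Depth of variant-supporting reads">
##FORMAT=<ID=FREQ,Number=1,Type=String,Description="Variant allele frequency (percent)">
##FORMAT=<ID=ABQ,Number=1,Type=Float,Description="Mean base quality of variant reads">
##FORMAT=<ID=PVAL,Number=1,Type=Float,Description="SNV call p-value">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(cs: CallSet, path) -> None:
    """Write a CallSet's variants as a minimal VCF 4.2 with VarScan-style
    FORMAT fields, in (chrom, pos) order."""
    def dot(x, fmt="{}"):
        return "." if x is None else fmt.format(x)

    lines = [_VCF_HEADER.format(sample=cs.replicate_id)]
    for key in sorted(cs.variants):
        v = cs.variants[key]
        if v.genotype[0] == v.genotype[1]:
            gt = "1/1"
        elif v.ref in v.genotype:
            gt = "0/1"
        else:  # het between two non-reference alleles
            gt = "1/2"
        freq = "." if v.vaf is None else f"{v.vaf * 100:.4f}%"
        sample = ":".join([
            gt,
            dot(None if v.coverage is None else int(v.coverage)),
            dot(None if v.vac is None else int(v.vac)),
            freq,
            dot(v.vaq, "{:.4f}"),
            dot(v.pvalue, "{:.6g}"),
        ])
        alt = v.variant_allele
        if gt == "1/2":
            other = next(a for a in v.genotype if a != v.variant_allele)
            alt = f"{v.variant_allele},{other}"
        info = "." if v.coverage is None else f"DP={int(v.coverage)}"
        lines.append("\t".join([
            v.chrom, str(v.pos), ".", v.ref, alt, ".", "PASS", info,
            "GT:DP:AD:FREQ:ABQ:PVAL", sample,
        ]) + "\n")
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# Consensus dialect

CONSENSUS_COLUMNS = ["chrom", "pos", "ref", "call", "coverage", "vac", "vaf", "vaq", "pvalue"]


def read_consensus_table(path, sample_id: Optional[str] = None,
                         replicate_id: Optional[str] = None) -> CallSet:
    """Read a per-position consensus TSV into a CallSet.

    Dialect: tab-separated, header ``#chrom pos ref call coverage vac vaf
    vaq pvalue``, ``.`` for missing.  ``call`` is a base (homozygous), an
    IUPAC two-base code (heterozygous) or ``N`` (ambiguous).  Every row
    yields a consensus entry; rows whose call is a non-reference,
    non-``N`` genotype additionally yield a VariantCall.  Rows violating
    ``vac <= coverage`` are rejected with their line number.
    """
    path = str(path)
    df = pd.read_csv(path, sep="\t", comment=None, na_values=["."],
                     dtype={"chrom": str, "call": str, "ref": str})
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = [c for c in CONSENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise ConsensusSchemaError(f"{path}: missing columns {missing}")
    if not np.issubdtype(df["coverage"].dtype, np.number):
        bad = df.index[pd.to_numeric(df["coverage"], errors="coerce").isna()
                       & df["coverage"].notna()]
        line = int(bad[0]) + 2 if len(bad) else "?"
        raise ConsensusRowError(f"{path}: non-numeric coverage at line {line}")
    bad = df.index[(df["vac"] > df["coverage"]) & df["vac"].notna() & df["coverage"].notna()]
    if len(bad):
        raise ConsensusRowError(
            f"{path}: vac > coverage at line {int(bad[0]) + 2}")
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        raise ConsensusRowError(f"{path}: duplicate position at line {int(df.index[dup][0]) + 2}")

    cs = CallSet(sample_id=sample_id or Path(path).stem,
                 replicate_id=replicate_id or Path(path).stem,
                 consensus=df.set_index(["chrom", "pos"]).sort_index())
    variant_rows = df[(df["call"] != "N") & (df["call"] != df["ref"]) & df["ref"].notna()]
    for row in variant_rows.itertuples(index=False):
        genotype = genotype_from_call(row.call, row.ref)
        if not any(a != row.ref for a in genotype):
            continue  # homozygous-reference symbol spelled oddly; not a variant
        non_ref = [a for a in genotype if a != row.ref]
        cs.add(VariantCall(
            chrom=row.chrom, pos=int(row.pos), ref=row.ref, genotype=genotype,
            variant_allele=non_ref[0],
            coverage=None if pd.isna(row.coverage) else float(row.coverage),
            vac=None if pd.isna(row.vac) else float(row.vac),
            vaf=None if pd.isna(row.vaf) else float(row.vaf),
            vaq=None if pd.isna(row.vaq) else float(row.vaq),
            pvalue=None if pd.isna(row.pvalue) else float(row.pvalue),
        ))
    return cs


def write_consensus_table(cs: CallSet, path) -> None:
    """Write the consensus table in the TSV dialect (round-trip exact)."""
    if cs.consensus is None:
        raise ValueError("CallSet has no consensus table")
    df = cs.consensus.reset_index()[CONSENSUS_COLUMNS]
    out = df.to_csv(sep="\t", index=False, na_rep=".")
    Path(path).write_text("#" + out)


# ---------------------------------------------------------------------------
# Auxiliary tracks

@dataclass
class TargetRegions:
    """Capture-target intervals, 1-based closed, per chromosome."""

    intervals: dict[str, list[tuple[int, int]]]

    @classmethod
    def read_bed(cls, path) -> "TargetRegions":
        """Read a BED file (0-based half-open) and convert to 1-based closed."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"],
                         dtype={"chrom": str})
        ivals: dict[str, list[tuple[int, int]]] = {}
        for row in df.itertuples(index=False):
            ivals.setdefault(row.chrom, []).append((int(row.start) + 1, int(row.end)))
        for chrom in ivals:
            ivals[chrom].sort()
        return cls(ivals)

    def __contains__(self, key: tuple[str, int]) -> bool:
        chrom, pos = key
        ivs = self.intervals.get(chrom)
        if not ivs:
            return False
        i = bisect_right(ivs, (pos, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= pos <= ivs[i][1]


@dataclass
class GCTrack:
    """Windowed GC-content track: TSV ``chrom start end gc_fraction``
    (0-based half-open windows)."""

    windows: pd.DataFrame  # columns chrom, start, end, gc_fraction

    @classmethod
    def read(cls, path) -> "GCTrack":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["chrom", "start", "end", "gc_fraction"],
                         dtype={"chrom": str})
        if df.iloc[0]["gc_fraction"] == "gc_fraction":  # header present
            df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
        return cls(df.sort_values(["chrom", "start"]).reset_index(drop=True))

    def gc_at(self, chrom: str, pos: int) -> Optional[float]:
        """GC fraction of the window containing 1-based position ``pos``."""
        sub = self.windows[self.windows["chrom"] == chrom]
        starts = sub["start"].to_numpy()
        i = np.searchsorted(starts, pos - 1, side="right") - 1
        if i < 0:
            return None
        row = sub.iloc[i]
        if row["start"] <= pos - 1 < row["end"]:
            return float(row["gc_fraction"])
        return None


# ---------------------------------------------------------------------------

def classify_hfi(v: VariantCall) -> bool:
    """High-functional-importance flag: Mutation Assessor category high or
    medium, or a stopgain/stoploss exonic change.  Unknown fields count as
    not-HFI."""
    if v.ma_category in ("high", "medium"):
        return True
    if v.exonic_class in ("stopgain", "stoploss"):
        return True
    return False
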