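"""UMI-tagged reads → cleaned clonotype tables.

Processing order mirrors a molecular-barcoded TCR RNA-seq analysis:

1. :func:`demultiplex` — split pooled reads on sample barcodes.
2. :func:`group_by_umi` — collect reads sharing a 12-bp UMI.
3. :func:`build_consensus` — per-UMI majority-vote consensus, requiring a
   minimum of 3 supporting reads and a UMI-region quality floor of 10;
   conflicting sequences under one UMI are split into separate consensus
   records when each variant independently clears the read floor.
4. :func:`annotate` — V/J assignment by near-exact tag lookup against the
   mini-reference, CDR3 extraction and translation.
5. (cross-sample decontamination; see :mod:`repseq.decontamination`)
6. :func:`filter_functional` — drop CDR3s with stop codons and records
   below the read-support floor.
7. :func:`collapse` — collapse to clonotypes, counting distinct UMIs.

A unique TCR (clonotype) is a unique combination of V, J and CDR3 amino
acid sequence; overlap analyses additionally key on the CDR3 nucleotide
sequence. Both keys are supported (``key_level`` = ``"aa"`` | ``"nt"``).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import MiniReference, hamming

logger = logging.getLogger(__name__)

UMI_LENGTH = 12
MIN_READS_PER_UMI = 3
MIN_UMI_QUALITY = 10.0
STOP_SYMBOL = "*"

CHAINS = ("alpha", "beta")

#: AIRR Rearrangement-style column layout of clonotype tables
TABLE_COLUMNS = ("chain", "v_call", "j_call", "junction", "junction_aa",
                 "duplicate_count")


class PipelineError(ValueError):
    """Raised for invalid pipeline inputs or configuration."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class SampleId:
    """Identity of one sequencing sample: donor, visit, subset, chain."""

    donor: str
    visit: int
    subset: str
    chain: str

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise PipelineError(f"chain must be one of {CHAINS}, "
                                f"got {self.chain!r}")

    @property
    def label(self) -> str:
        return f"{self.donor}.v{self.visit}.{self.subset}.{self.chain}"


@dataclass(frozen=True)
class TCRSequence:
    """A clonotype key: chain, V gene, J gene, CDR3 (aa and nt)."""

    chain: str
    v_gene: str
    j_gene: str
    cdr3_aa: str
    cdr3_nt: str

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise PipelineError(f"chain must be one of {CHAINS}")
        if len(self.cdr3_nt) != 3 * len(self.cdr3_aa):
            raise PipelineError("cdr3_nt length must be 3× cdr3_aa length")
        if str(Seq(self.cdr3_nt).translate()) != self.cdr3_aa:
            raise PipelineError("cdr3_nt does not translate to cdr3_aa")

    def key(self, level: str = "aa") -> tuple:
        if level == "aa":
            return (self.chain, self.v_gene, self.j_gene, self.cdr3_aa)
        if level == "nt":
            return (self.chain, self.v_gene, self.j_gene, self.cdr3_aa,
                    self.cdr3_nt)
        raise PipelineError(f"unknown key level {level!r}")


@dataclass
class UMIGroup:
    """All reads from one sample sharing one UMI."""

    umi: str
    sample: SampleId
    sequences: list[str]
    qualities: list[list[int]]
    umi_qualities: list[float]
    pcr_time: Optional[int] = None

    def __post_init__(self) -> None:
        if not (len(self.sequences) == len(self.qualities)
                == len(self.umi_qualities)):
            raise PipelineError("per-read lists must have equal length")

    @property
    def n_reads(self) -> int:
        return len(self.sequences)


@dataclass
class ConsensusRecord:
    """Majority-vote consensus for one (UMI, sequence-variant) cluster."""

    sample: SampleId
    umi: str
    sequence: str
    n_reads: int
    pcr_time: Optional[int] = None


@dataclass
class AnnotatedRecord:
    """A consensus record with V/J/CDR3 annotation attached."""

    sample: SampleId
    umi: str
    tcr: TCRSequence
    n_reads: int
    pcr_time: Optional[int] = None


@dataclass
class ClonotypeTable:
    """Per-sample clonotypes with UMI counts (one repertoire)."""

    sample: SampleId
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(TABLE_COLUMNS) - set(self.df.columns)
        if missing:
            raise PipelineError(f"clonotype table missing columns {missing}")
        if len(self.df) and (self.df["duplicate_count"] < 1).any():
            raise PipelineError("umi counts must be >= 1")

    @property
    def total_umi(self) -> int:
        return int(self.df["duplicate_count"].sum())

    @property
    def n_clonotypes(self) -> int:
        return len(self.df)

    def keys(self, level: str = "aa") -> set:
        cols = ["chain", "v_call", "j_call", "junction_aa"]
        if level == "nt":
            cols.append("junction")
        elif level != "aa":
            raise PipelineError(f"unknown key level {level!r}")
        return set(map(tuple, self.df[cols].itertuples(index=False)))

    def counts(self, level: str = "aa") -> dict:
        cols = ["chain", "v_call", "j_call", "junction_aa"]
        if level == "nt":
            cols.append("junction")
        out: dict = defaultdict(int)
        for row in self.df.itertuples(index=False):
            k = tuple(getattr(row, c) for c in cols)
            out[k] += int(row.duplicate_count)
        return dict(out)

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "sample", self.sample.label)
        out.insert(1, "donor", self.sample.donor)
        out.insert(2, "visit", self.sample.visit)
        out.insert(3, "subset", self.sample.subset)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ClonotypeTable":
        df = pd.read_csv(path, sep="\t")
        sample = SampleId(str(df["donor"].iloc[0]), int(df["visit"].iloc[0]),
                          str(df["subset"].iloc[0]), str(df["chain"].iloc[0]))
        return cls(sample, df[list(TABLE_COLUMNS)].reset_index(drop=True))


# ---------------------------------------------------------------------------
# demultiplexing and UMI grouping
# ---------------------------------------------------------------------------

@dataclass
class DemuxResult:
    by_sample: dict  # SampleId -> list[SeqRecord]
    undetermined: list = field(default_factory=list)

    @property
    def n_undetermined(self) -> int:
        return len(self.undetermined)


def demultiplex(reads: Iterable[SeqRecord],
                barcode_map: dict) -> DemuxResult:
    """Split pooled reads on exact sample-barcode prefixes.

    ``barcode_map`` maps barcode sequence → :class:`SampleId`. Barcodes must
    be distinct and of equal length; reads whose prefix matches no barcode
    are routed to ``undetermined`` and counted.
    """
    if not barcode_map:
        raise PipelineError("empty barcode map")
    lengths = {len(b) for b in barcode_map}
    if len(lengths) != 1:
        raise PipelineError("barcodes must share one length")
    if len(set(barcode_map.values())) != len(barcode_map):
        raise PipelineError("duplicate sample assignment in barcode map")
    bc_len = lengths.pop()
    result = DemuxResult(by_sample={s: [] for s in barcode_map.values()})
    for read in reads:
        sample = barcode_map.get(str(read.seq[:bc_len]))
        if sample is None:
            result.undetermined.append(read)
        else:
            result.by_sample[sample].append(read)
    if result.undetermined:
        logger.info("demultiplex: %d reads undetermined",
                    len(result.undetermined))
    return result


def group_by_umi(reads: Sequence[SeqRecord], sample: SampleId,
                 barcode_length: int,
                 pcr_time: Optional[int] = None) -> list[UMIGroup]:
    """Strip barcode + 12-bp UMI and bucket reads by UMI.

    The stored sequence/quality cover the TCR region only; the mean Phred
    over the UMI region is kept per read for the consensus quality filter.
    Groups are returned in first-seen order for determinism.
    """
    buckets: dict[str, UMIGroup] = {}
    for read in reads:
        seq = str(read.seq)
        qual = read.letter_annotations.get("phred_quality")
        if qual is None:
            qual = [40] * len(seq)
        umi = seq[barcode_length:barcode_length + UMI_LENGTH]
        if len(umi) < UMI_LENGTH:
            raise PipelineError("read too short to contain a 12-bp UMI")
        start = barcode_length + UMI_LENGTH
        group = buckets.get(umi)
        if group is None:
            group = buckets[umi] = UMIGroup(umi, sample, [], [], [],
                                            pcr_time=pcr_time)
        group.sequences.append(seq[start:])
        group.qualities.append(list(qual[start:]))
        group.umi_qualities.append(
            float(np.mean(qual[barcode_length:start])))
    return list(buckets.values())


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _majority_vote(sequences: Sequence[str]) -> str:
    """Position-wise majority base; ties resolved to the lexicographically
    smallest tied base for determinism."""
    length = len(sequences[0])
    out = []
    for pos in range(length):
        counts = Counter(s[pos] for s in sequences)
        top = max(counts.values())
        out.append(min(b for b, c in counts.items() if c == top))
    return "".join(out)


def build_consensus(group: UMIGroup, min_reads: int = MIN_READS_PER_UMI,
                    min_quality: float = MIN_UMI_QUALITY
                    ) -> list[ConsensusRecord]:
    """Per-UMI consensus with conflict splitting.

    Reads whose mean UMI-region Phred falls below ``min_quality`` are
    dropped first. Remaining reads are clustered by sequence identity
    (<=1 mismatch joins a cluster; length mismatch separates); each cluster
    with at least ``min_reads`` reads yields its own majority-vote
    consensus, so genuinely conflicting sequences under one UMI are kept
    apart rather than averaged. An empty result is valid.
    """
    if group.n_reads == 0:
        raise PipelineError("empty UMI group")
    kept = [(s, q) for s, q, uq in zip(group.sequences, group.qualities,
                                       group.umi_qualities)
            if uq >= min_quality]
    clusters: list[list[str]] = []
    for seq, _ in kept:
        for cluster in clusters:
            rep = cluster[0]
            if len(rep) == len(seq) and hamming(rep, seq) <= 1:
                cluster.append(seq)
                break
        else:
            clusters.append([seq])
    records = []
    for cluster in clusters:
        if len(cluster) >= min_reads:
            records.append(ConsensusRecord(
                sample=group.sample, umi=group.umi,
                sequence=_majority_vote(cluster), n_reads=len(cluster),
                pcr_time=group.pcr_time))
    return records


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate(record: ConsensusRecord,
             reference: MiniReference) -> Optional[AnnotatedRecord]:
    """Assign V/J by tag lookup and extract/translate the CDR3.

    Returns None (record unannotated) if either tag fails to match within
    the reference's mismatch tolerance, the matched V and J disagree on
    chain, or the intervening CDR3 is absent or out of frame.
    """
    seq = record.sequence
    tl = reference.tag_length
    if len(seq) < 2 * tl + 3:
        return None
    v = reference.match_v(seq[:tl])
    j = reference.match_j(seq[-tl:])
    if v is None or j is None or v.chain != j.chain:
        return None
    cdr3_nt = seq[tl:-tl]
    if len(cdr3_nt) % 3 != 0:
        return None
    cdr3_aa = str(Seq(cdr3_nt).translate())
    tcr = TCRSequence(chain=v.chain, v_gene=v.name, j_gene=j.name,
                      cdr3_aa=cdr3_aa, cdr3_nt=cdr3_nt)
    return AnnotatedRecord(sample=record.sample, umi=record.umi, tcr=tcr,
                           n_reads=record.n_reads, pcr_time=record.pcr_time)


def annotate_all(records: Iterable[ConsensusRecord],
                 reference: MiniReference
                 ) -> tuple[list[AnnotatedRecord], int]:
    """Annotate a batch; returns (annotated, n_dropped)."""
    annotated, dropped = [], 0
    for rec in records:
        out = annotate(rec, reference)
        if out is None:
            dropped += 1
        else:
            annotated.append(out)
    if dropped:
        logger.info("annotate: %d records unannotated and dropped", dropped)
    return annotated, dropped


# ---------------------------------------------------------------------------
# functional filter and clonotype collapse
# ---------------------------------------------------------------------------

def filter_functional(records: Iterable[AnnotatedRecord],
                      min_reads: int = MIN_READS_PER_UMI
                      ) -> list[AnnotatedRecord]:
    """Keep functional records: no stop codon in CDR3aa, >= min_reads."""
    return [r for r in records
            if STOP_SYMBOL not in r.tcr.cdr3_aa and r.n_reads >= min_reads]


def collapse(records: Sequence[AnnotatedRecord],
             key_level: str = "aa") -> ClonotypeTable:
    """Collapse one sample's records to a clonotype table.

    One row per clonotype key; ``duplicate_count`` is the number of
    distinct UMIs supporting the key. The CDR3nt column holds the first
    observed nucleotide variant when collapsing at amino-acid level.
    """
    if not records:
        raise PipelineError("cannot collapse zero records")
    samples = {r.sample for r in records}
    if len(samples) != 1:
        raise PipelineError("collapse requires records from a single sample")
    sample = samples.pop()
    umis: dict[tuple, set] = defaultdict(set)
    first_nt: dict[tuple, str] = {}
    for r in records:
        k = r.tcr.key(key_level)
        umis[k].add(r.umi)
        first_nt.setdefault(k, r.tcr.cdr3_nt)
    rows = []
    for k in umis:
        chain, v, j, aa = k[:4]
        nt = k[4] if key_level == "nt" else first_nt[k]
        rows.append((chain, v, j, nt, aa, len(umis[k])))
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    df = df.sort_values(["v_call", "j_call", "junction_aa", "junction"],
                        kind="mergesort").reset_index(drop=True)
    return ClonotypeTable(sample, df)


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def preprocess(reads: Iterable[SeqRecord], barcode_map: dict,
               reference: MiniReference, pcr_times: Optional[dict] = None,
               min_reads: int = MIN_READS_PER_UMI,
               min_quality: float = MIN_UMI_QUALITY,
               decontaminate: bool = True,
               key_level: str = "aa") -> dict:
    """Pooled FASTQ reads → per-sample clonotype tables.

    ``pcr_times`` maps SampleId → PCR amplification batch (ordinal); it is
    required when ``decontaminate`` is on. Returns
    ``{"tables": {SampleId: ClonotypeTable}, "report": {...}}``.
    """
    from . import decontamination

    lengths = {len(b) for b in barcode_map}
    if len(lengths) != 1:
        raise PipelineError("barcodes must share one length")
    bc_len = lengths.pop()
    demux = demultiplex(reads, barcode_map)
    annotated: list[AnnotatedRecord] = []
    n_unannotated = 0
    for sample, sample_reads in demux.by_sample.items():
        pcr_time = (pcr_times or {}).get(sample)
        for group in group_by_umi(sample_reads, sample, bc_len,
                                  pcr_time=pcr_time):
            for cons in build_consensus(group, min_reads=min_reads,
                                        min_quality=min_quality):
                out = annotate(cons, reference)
                if out is None:
                    n_unannotated += 1
                else:
                    annotated.append(out)
    report = {"n_undetermined": demux.n_undetermined,
              "n_unannotated": n_unannotated}
    if decontaminate:
        annotated, decon_report = decontamination.remove_contaminants(
            annotated)
        report["decontamination"] = decon_report
    functional = filter_functional(annotated, min_reads=min_reads)
    report["n_nonfunctional"] = len(annotated) - len(functional)
    by_sample: dict[SampleId, list[AnnotatedRecord]] = defaultdict(list)
    for r in functional:
        by_sample[r.sample].append(r)
    tables = {s: collapse(recs, key_level=key_level)
              for s, recs in by_sample.items()}
    return {"tables": tables, "report": report}
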