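"""Cross-sample contamination removal via UMI + TCR collisions.

A 12-bp UMI combined with a TCR nucleotide sequence is effectively a
molecular fingerprint: with UMI diversity ~1e6 and TCR diversity ~1e4 per
sample, the chance that two samples independently produce the same
(UMI, TCR) pair is ~1e-10. Observing the same pair in different samples
therefore indicates physical carry-over. The record amplified earliest is
treated as the true source and retained; all later copies are removed.
If the earliest PCR amplification time is shared by several samples, the
source is ambiguous and every record in the collision group is removed.

Collisions are keyed on the nucleotide-level clonotype
(chain, V, J, CDR3nt): contamination is a property of physical molecules,
and collapsing to amino acids would over-remove convergent clones.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Sequence

from .umi_pipeline import AnnotatedRecord

logger = logging.getLogger(__name__)


class DecontaminationError(ValueError):
    pass


def _collision_key(record: AnnotatedRecord) -> tuple:
    t = record.tcr
    return (record.umi, t.chain, t.v_gene, t.j_gene, t.cdr3_nt)


def find_collisions(records: Iterable[AnnotatedRecord]
                    ) -> list[list[AnnotatedRecord]]:
    """Group records sharing (UMI, TCRnt) across two or more samples.

    Every record must carry a PCR amplification time; resolution is
    impossible without one.
    """
    groups: dict[tuple, list[AnnotatedRecord]] = defaultdict(list)
    for rec in records:
        if rec.pcr_time is None:
            raise DecontaminationError(
                "record lacks pcr_time; cannot assess contamination")
        groups[_collision_key(rec)].append(rec)
    return [g for g in groups.values()
            if len({r.sample for r in g}) >= 2]


def resolve(group: Sequence[AnnotatedRecord]
            ) -> tuple[list[AnnotatedRecord], list[AnnotatedRecord]]:
    """Apply the earliest-PCR-time rule to one collision group.

    Returns (kept, removed). A unique earliest time keeps exactly that
    record; a tie at the earliest time removes the whole group.
    """
    if len(group) < 2:
        raise DecontaminationError("collision group must have >= 2 records")
    times = [r.pcr_time for r in group]
    earliest = min(times)
    if times.count(earliest) == 1:
        kept = [r for r in group if r.pcr_time == earliest]
        removed = [r for r in group if r.pcr_time != earliest]
    else:
        kept, removed = [], list(group)
    return kept, removed


def remove_contaminants(records: Sequence[AnnotatedRecord]
                        ) -> tuple[list[AnnotatedRecord], dict]:
    """Drop contaminated records from a cross-sample record set.

    Returns (clean records in input order, report). The report carries the
    number of collision groups and per-sample removed counts.
    """
    collisions = find_collisions(records)
    removed_ids = set()
    removed_by_sample: dict[str, int] = defaultdict(int)
    for group in collisions:
        _, removed = resolve(group)
        for rec in removed:
            removed_ids.add(id(rec))
            removed_by_sample[rec.sample.label] += 1
    clean = [r for r in records if id(r) not in removed_ids]
    report = {"n_collision_groups": len(collisions),
              "n_removed": len(records) - len(clean),
              "removed_by_sample": dict(removed_by_sample)}
    if report["n_removed"]:
        logger.info("decontamination removed %d records in %d groups",
                    report["n_removed"], len(collisions))
    return clean, report


def collision_probability(umi_diversity: float,
                          tcr_diversity: float) -> float:
    """Chance that a specific (UMI, TCR) pair recurs independently.

    1/(umi_diversity × tcr_diversity); at typical per-sample diversities
    of 1e6 UMIs and 1e4 TCRs this is 1e-10.
    """
    if umi_diversity < 1 or tcr_diversity < 1:
        raise DecontaminationError("diversities must be >= 1")
    return 1.0 / (umi_diversity * tcr_diversity)
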