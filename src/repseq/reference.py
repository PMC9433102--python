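"""Mini V/J germline reference used for synthetic reads and annotation.

Real TCR annotation aligns reads against the IMGT germline library. This
package instead carries a small synthetic reference: a handful of V and J
segments per chain, each identified by a unique 20-nt tag flanking the CDR3.
Tags are generated deterministically and kept mutually distant (Hamming
distance >= 2*tolerance + 1) so that near-exact tag lookup is unambiguous
at the configured mismatch tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

NUCLEOTIDES = "ACGT"

#: default mismatch tolerance for tag lookup (tags are 20 nt, synthetic
#: per-base error rates are <=1%, so 2 mismatches is generous)
DEFAULT_MAX_MISMATCH = 2


@dataclass(frozen=True)
class GeneSegment:
    """One V or J germline segment with its identification tag."""

    name: str
    chain: str  # "alpha" | "beta"
    tag: str


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def _draw_distant_tags(rng: np.random.Generator, n: int, length: int,
                       min_dist: int) -> list[str]:
    """Rejection-sample ``n`` tags pairwise >= min_dist apart."""
    tags: list[str] = []
    while len(tags) < n:
        cand = "".join(rng.choice(list(NUCLEOTIDES), size=length))
        if all(hamming(cand, t) >= min_dist for t in tags):
            tags.append(cand)
    return tags


@dataclass
class MiniReference:
    """Lookup tables mapping 20-nt tags to V/J segment names.

    V segments (both chains pooled) share one tag namespace, as do J
    segments: a read's chain is inferred from which segment its V tag
    matches, and annotation requires the matched V and J to agree on chain.
    """

    v_segments: list[GeneSegment]
    j_segments: list[GeneSegment]
    tag_length: int = 20
    max_mismatch: int = DEFAULT_MAX_MISMATCH
    _v_by_name: dict = field(init=False, repr=False)
    _j_by_name: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._v_by_name = {s.name: s for s in self.v_segments}
        self._j_by_name = {s.name: s for s in self.j_segments}
        if len(self._v_by_name) != len(self.v_segments):
            raise ValueError("duplicate V segment names")
        if len(self._j_by_name) != len(self.j_segments):
            raise ValueError("duplicate J segment names")

    def v(self, name: str) -> GeneSegment:
        return self._v_by_name[name]

    def j(self, name: str) -> GeneSegment:
        return self._j_by_name[name]

    def v_names(self, chain: str) -> list[str]:
        return [s.name for s in self.v_segments if s.chain == chain]

    def j_names(self, chain: str) -> list[str]:
        return [s.name for s in self.j_segments if s.chain == chain]

    def _match(self, segments: Sequence[GeneSegment],
               observed: str) -> Optional[GeneSegment]:
        if len(observed) != self.tag_length:
            return None
        best: Optional[GeneSegment] = None
        best_d = self.max_mismatch + 1
        for seg in segments:
            d = hamming(observed, seg.tag)
            if d < best_d:
                best, best_d = seg, d
        return best

    def match_v(self, observed: str) -> Optional[GeneSegment]:
        """Best V segment within the mismatch tolerance, else None."""
        return self._match(self.v_segments, observed)

    def match_j(self, observed: str) -> Optional[GeneSegment]:
        """Best J segment within the mismatch tolerance, else None."""
        return self._match(self.j_segments, observed)


def default_reference(n_v: int = 20, n_j: int = 10, tag_length: int = 20,
                      max_mismatch: int = DEFAULT_MAX_MISMATCH,
                      seed: int = 1158122) -> MiniReference:
    """Build the bundled deterministic mini-reference.

    20 V and 10 J segments per chain by default. Tags are kept
    >= 2*max_mismatch + 1 apart so lookup at the tolerance is unambiguous.
    """
    rng = np.random.default_rng(seed)
    min_dist = 2 * max_mismatch + 1
    v_tags = _draw_distant_tags(rng, 2 * n_v, tag_length, min_dist)
    j_tags = _draw_distant_tags(rng, 2 * n_j, tag_length, min_dist)
    v_segments, j_segments = [], []
    for ci, chain in enumerate(("alpha", "beta")):
        prefix = "TRA" if chain == "alpha" else "TRB"
        for i in range(n_v):
            v_segments.append(GeneSegment(f"{prefix}V{i + 1}", chain,
                                          v_tags[ci * n_v + i]))
        for i in range(n_j):
            j_segments.append(GeneSegment(f"{prefix}J{i + 1}", chain,
                                          j_tags[ci * n_j + i]))
    return MiniReference(v_segments, j_segments, tag_length=tag_length,
                         max_mismatch=max_mismatch)
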