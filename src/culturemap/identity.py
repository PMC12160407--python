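"""Best-hit ungapped percent identity under a 100% query-coverage contract.

Each community ASV (query, typically a ~250 nt V4 amplicon) is slid along every
isolate sequence (subject, typically full-length 16S) on both strands; identity
is the maximum fraction of matching positions over all ungapped placements that
cover the full query.  This replaces a megablast-style heuristic search with an
exact exhaustive scan, which is feasible at the scale of a few thousand ASVs
against a few hundred isolates.

Conventions (fixed for reproducibility):

* ``N`` matches nothing, including another ``N``.
* Ties are broken by smallest subject offset; the forward strand is preferred
  over the reverse complement at equal identity; subjects are compared in
  lexicographic id order and the first maximum wins.
* The identity denominator is the query length (equivalent to the alignment
  length under full ungapped coverage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .records import SequenceSet

FORWARD = "forward"
REVERSE = "reverse"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base -> one-hot channel; N maps to the all-zero row so it matches nothing
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


@dataclass(frozen=True)
class IdentityHit:
    """Best ungapped hit of one community ASV against the isolate set.

    ``subject_id``/``identity``/``offset``/``strand`` are ``None`` when no
    subject is at least as long as the query (the full-coverage contract
    cannot be met).
    """

    query_id: str
    subject_id: Optional[str]
    identity: Optional[float]
    offset: Optional[int]
    strand: Optional[str]

    @property
    def matched(self) -> bool:
        return self.subject_id is not None


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ``{A,C,G,T,N}`` alphabet."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"illegal characters for reverse complement: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def _encode_onehot(seq: str) -> np.ndarray:
    """(L, 4) float32 one-hot; N (or any non-ACGT) rows are all zero."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    onehot = np.zeros((len(seq), 4), dtype=np.float32)
    valid = codes < 4
    onehot[np.nonzero(valid)[0], codes[valid]] = 1.0
    return onehot


def _match_counts(query_onehot: np.ndarray, subject_onehot: np.ndarray) -> np.ndarray:
    """Matches of the query against every full-coverage window of the subject.

    Returns an int array of length ``len(subject) - len(query) + 1``.
    """
    n = query_onehot.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(subject_onehot, (n, 4))
    windows = windows.reshape(-1, n * 4)
    counts = windows @ query_onehot.reshape(-1)
    return np.rint(counts).astype(np.int64)


def sliding_identity(
    query: str, subject: str
) -> Optional[tuple[float, int, str]]:
    """Maximum ungapped percent identity of ``query`` inside ``subject``.

    Scans every offset on both strands; returns ``(identity, offset, strand)``
    with the tie-break conventions above, or ``None`` when the query is longer
    than the subject (no placement covers the query fully).
    """
    if not query or not subject:
        raise ValueError("query and subject must be non-empty")
    if len(query) > len(subject):
        return None
    subject_oh = _encode_onehot(subject)
    fwd = _match_counts(_encode_onehot(query), subject_oh)
    rev = _match_counts(_encode_onehot(reverse_complement(query)), subject_oh)
    off_f = int(np.argmax(fwd))
    off_r = int(np.argmax(rev))
    if rev[off_r] > fwd[off_f]:
        best, offset, strand = int(rev[off_r]), off_r, REVERSE
    else:
        best, offset, strand = int(fwd[off_f]), off_f, FORWARD
    return 100.0 * best / len(query), offset, strand


def best_hits(community: SequenceSet, isolates: SequenceSet) -> list[IdentityHit]:
    """Best isolate hit for every community ASV.

    One :class:`IdentityHit` per community record, in community order.  The
    subject is chosen by maximum identity with ties broken by lexicographically
    smallest subject id; queries longer than every subject get a no-hit record.
    """
    if len(community) == 0 or len(isolates) == 0:
        raise ValueError("community and isolate sets must be non-empty")

    queries = list(community)
    lengths = sorted({len(q) for q in queries})
    by_len = {L: [q for q in queries if len(q) == L] for L in lengths}

    # query one-hots, flat, per length group (forward + reverse-complement)
    enc: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for L, group in by_len.items():
        f = np.stack([_encode_onehot(q.sequence).reshape(-1) for q in group])
        r = np.stack(
            [
                _encode_onehot(reverse_complement(q.sequence)).reshape(-1)
                for q in group
            ]
        )
        enc[L] = (f, r)

    best: dict[str, IdentityHit] = {
        q.id: IdentityHit(q.id, None, None, None, None) for q in queries
    }
    best_count: dict[str, int] = {q.id: -1 for q in queries}

    for subj in sorted(isolates, key=lambda r: r.id):
        subj_oh = _encode_onehot(subj.sequence)
        for L, group in by_len.items():
            if L > len(subj):
                continue
            windows = np.lib.stride_tricks.sliding_window_view(subj_oh, (L, 4))
            windows = windows.reshape(-1, L * 4)
            qf, qr = enc[L]
            cf = windows @ qf.T  # (n_offsets, n_queries)
            cr = windows @ qr.T
            off_f = np.argmax(cf, axis=0)
            off_r = np.argmax(cr, axis=0)
            nq = len(group)
            mf = np.rint(cf[off_f, np.arange(nq)]).astype(np.int64)
            mr = np.rint(cr[off_r, np.arange(nq)]).astype(np.int64)
            for i, q in enumerate(group):
                if mr[i] > mf[i]:
                    count, offset, strand = int(mr[i]), int(off_r[i]), REVERSE
                else:
                    count, offset, strand = int(mf[i]), int(off_f[i]), FORWARD
                if count > best_count[q.id]:
                    best_count[q.id] = count
                    best[q.id] = IdentityHit(
                        q.id, subj.id, 100.0 * count / L, offset, strand
                    )
    return [best[q.id] for q in queries]
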