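"""Low-level DNA encoding and an exact seed-and-verify substring index.

The mapper guarantees *all-hits* semantics under a Hamming (substitution
only) distance cap: every genomic window, on either strand, whose distance
to the query is within the cap is reported.  Exactness comes from the
pigeonhole principle: a query allowed ``k`` mismatches is split into
``k + 1`` disjoint segments, at least one of which must match the genome
exactly; each segment's leading q-mer is looked up in a sorted k-mer table
and every candidate diagonal is then verified by direct comparison.

Queries too short to carry ``k + 1`` seeds of q bases fall back to a full
sliding-window scan, so the index is exact for every input size.
"""

from __future__ import annotations

import numpy as np

#: seed length; 4^12 = 16.7M possible codes, stored as int64
SEED_Q = 12

# base -> small integer; N maps to 4 (never equal to a real base), anything
# else to 5 so that N-vs-N in query-vs-genome still counts as a mismatch
_CODES = np.full(256, 5, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i
    _CODES[_b + 32] = _i  # lowercase
_CODES[ord("N")] = 4
_CODES[ord("n")] = 4

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code array (A,C,G,T -> 0..3)."""
    return _CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeIndex:
    """Sorted q-mer index over a set of scaffolds.

    Scaffolds are concatenated with q sentinel positions between them so a
    single global coordinate system can be used; windows that touch a
    sentinel are excluded from the index and rejected at verification.
    """

    def __init__(self, scaffolds: dict[str, str], q: int = SEED_Q):
        self.q = q
        self.names: list[str] = list(scaffolds)
        starts, lengths, parts = [], [], []
        gap = np.full(q, 4, dtype=np.uint8)
        pos = 0
        for name in self.names:
            seq = scaffolds[name]
            starts.append(pos)
            lengths.append(len(seq))
            parts.append(encode(seq))
            parts.append(gap)
            pos += len(seq) + q
        self.codes = (
            np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint8)
        )
        self.starts = np.asarray(starts, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.int64)
        self._build()

    def _build(self) -> None:
        c = self.codes.astype(np.int64)
        n = len(c) - self.q + 1
        if n <= 0:
            self._sorted_kmers = np.zeros(0, dtype=np.int64)
            self._kmer_pos = np.zeros(0, dtype=np.int64)
            return
        kmers = np.zeros(n, dtype=np.int64)
        for j in range(self.q):
            kmers = kmers * 4 + c[j : j + n]
        bad = np.concatenate(([0], np.cumsum(c >= 4)))
        valid = (bad[self.q :] - bad[:-self.q]) == 0
        pos = np.nonzero(valid)[0]
        kv = kmers[pos]
        order = np.argsort(kv, kind="stable")
        self._sorted_kmers = kv[order]
        self._kmer_pos = pos[order]

    def lookup(self, code: int) -> np.ndarray:
        """Global positions of an exact q-mer (by numeric code)."""
        lo = np.searchsorted(self._sorted_kmers, code, side="left")
        hi = np.searchsorted(self._sorted_kmers, code, side="right")
        return self._kmer_pos[lo:hi]

    def find(
        self, query_codes: np.ndarray, max_mismatches: int
    ) -> list[tuple[int, int, int]]:
        """All (scaffold_index, local_start, n_mismatches) hits of a query.

        The query is given in encoded form and matched in the orientation
        supplied; callers handle strand by passing the reverse complement.
        """
        L = len(query_codes)
        if L == 0 or len(self.codes) == 0:
            return []
        n_seg = max_mismatches + 1
        seg_len = L // n_seg
        if seg_len < self.q:
            return self._scan(query_codes, max_mismatches)

        candidate_lists = []
        for i in range(n_seg):
            off = i * seg_len
            window = query_codes[off : off + self.q]
            if window.max() >= 4:
                # a segment containing N cannot be the exact segment
                continue
            code = 0
            for d in window:
                code = code * 4 + int(d)
            pos = self.lookup(code)
            if len(pos):
                candidate_lists.append(pos - off)
        if not candidate_lists:
            return []
        starts = np.unique(np.concatenate(candidate_lists))
        starts = starts[starts >= 0]
        return self._verify(starts, query_codes, max_mismatches)

    def _verify(
        self, starts: np.ndarray, query_codes: np.ndarray, k: int
    ) -> list[tuple[int, int, int]]:
        L = len(query_codes)
        hits = []
        for g in starts.tolist():
            sc = int(np.searchsorted(self.starts, g, side="right")) - 1
            if sc < 0:
                continue
            local = g - int(self.starts[sc])
            if local + L > int(self.lengths[sc]):
                continue
            mism = int(np.count_nonzero(self.codes[g : g + L] != query_codes))
            if mism <= k:
                hits.append((sc, local, mism))
        return hits

    def _scan(
        self, query_codes: np.ndarray, k: int
    ) -> list[tuple[int, int, int]]:
        """Sliding-window fallback for queries too short to seed."""
        L = len(query_codes)
        n = len(self.codes) - L + 1
        if n <= 0:
            return []
        mism = np.zeros(n, dtype=np.int64)
        for j in range(L):
            mism += self.codes[j : j + n] != query_codes[j]
        return self._verify(np.nonzero(mism <= k)[0], query_codes, k)
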