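"""Pairwise sequence distances: site-pattern counts, p-distance, K2P.

Sequences are compared column-by-column under pairwise deletion: any column
where either symbol is not one of A, C, G, T (gaps, Ns, IUPAC ambiguity
codes) is excluded from that pair's comparison.  Differences between two
purines (A<->G) or two pyrimidines (C<->T) are transitions; all other
differences are transversions.

With P = transitions/n and Q = transversions/n over the n jointly
unambiguous sites, the two-parameter corrected distance is

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

which is undefined (saturated) when either log argument is non-positive.
The uncorrected p-distance is simply P + Q.  d >= p always, with equality
only at p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BarcodeSequence

# A,G even; C,T odd -- a transition is "codes differ but share parity"
_CODE = np.full(256, 255, dtype=np.uint8)
_CODE[ord("A")], _CODE[ord("G")] = 0, 2
_CODE[ord("C")], _CODE[ord("T")] = 1, 3


class AlignmentError(ValueError):
    """Sequences not comparable (unequal length)."""


class SaturationError(ValueError):
    """K2P log argument non-positive; distance undefined."""


class UndefinedComparisonError(ValueError):
    """No jointly unambiguous sites between a pair."""


@dataclass(frozen=True)
class SitePatternCounts:
    """Joint site counts for one aligned pair."""

    n_compared: int
    matches: int
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        return self.transitions / self.n_compared

    @property
    def Q(self) -> float:
        return self.transversions / self.n_compared


def encode(seq: str | BarcodeSequence) -> np.ndarray:
    """Map a nucleotide string to uint8 codes (255 for ambiguous/gap)."""
    s = seq.seq if isinstance(seq, BarcodeSequence) else seq
    return _CODE[np.frombuffer(s.upper().encode(), dtype=np.uint8)]


def site_patterns(
    a: str | BarcodeSequence, b: str | BarcodeSequence
) -> SitePatternCounts:
    """Count matches, transitions and transversions for an aligned pair."""
    ca, cb = encode(a), encode(b)
    if ca.shape != cb.shape:
        raise AlignmentError(
            f"unequal lengths: {ca.size} vs {cb.size} (sequences must be "
            "aligned)")
    valid = (ca < 4) & (cb < 4)
    n = int(valid.sum())
    if n == 0:
        raise UndefinedComparisonError("no jointly unambiguous sites")
    diff = valid & (ca != cb)
    ts = int((diff & ((ca & 1) == (cb & 1))).sum())
    tv = int(diff.sum()) - ts
    return SitePatternCounts(
        n_compared=n, matches=n - ts - tv, transitions=ts, transversions=tv)


def p_distance(a, b) -> float:
    """Proportion of differing sites among jointly unambiguous columns."""
    c = site_patterns(a, b)
    return (c.transitions + c.transversions) / c.n_compared


def k2p_from_pq(P: float, Q: float) -> float:
    """Two-parameter distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"saturated pair: P={P:.4f}, Q={Q:.4f}")
    return -0.5 * np.log(w1 * np.sqrt(w2))


def k2p_distance(a, b) -> float:
    c = site_patterns(a, b)
    return k2p_from_pq(c.P, c.Q)


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with ordered labels."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("nonzero diagonal")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.values[i, j])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(["id"] + self.ids) + "\n")
            for i, name in enumerate(self.ids):
                row = "\t".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{name}\t{row}\n")


def encode_matrix(seqs: list[BarcodeSequence]) -> np.ndarray:
    """Stack equal-length sequences into an (n, L) uint8 code array."""
    codes = [encode(s) for s in seqs]
    lengths = {c.size for c in codes}
    if len(lengths) > 1:
        raise AlignmentError(
            f"sequences not aligned: lengths {sorted(lengths)}")
    return np.vstack(codes)


def matrix_from_codes(
    codes: np.ndarray, ids: list[str], metric: str = "k2p"
) -> DistanceMatrix:
    """All-pairs distances from an (n, L) code array."""
    if metric not in ("p", "k2p"):
        raise ValueError(f"unknown metric {metric!r}")
    n = codes.shape[0]
    m = np.zeros((n, n))
    valid = codes < 4
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nn = int(both.sum())
            if nn == 0:
                raise UndefinedComparisonError(
                    f"no comparable sites: {ids[i]} vs {ids[j]}")
            diff = both & (codes[i] != codes[j])
            nd = int(diff.sum())
            if metric == "p":
                m[i, j] = m[j, i] = nd / nn
            else:
                ts = int((diff & ((codes[i] & 1) == (codes[j] & 1))).sum())
                try:
                    m[i, j] = m[j, i] = k2p_from_pq(ts / nn, (nd - ts) / nn)
                except SaturationError as err:
                    raise SaturationError(
                        f"{ids[i]} vs {ids[j]}: {err}") from err
    return DistanceMatrix(ids=list(ids), values=m)


def pairwise_matrix(
    seqs: list[BarcodeSequence], metric: str = "k2p"
) -> DistanceMatrix:
    """All-pairs distance matrix, ``metric`` in {"p", "k2p"}.

    Raises :class:`SaturationError` naming the offending pair if any K2P
    distance is undefined.
    """
    return matrix_from_codes(
        encode_matrix(seqs), [s.id for s in seqs], metric)
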