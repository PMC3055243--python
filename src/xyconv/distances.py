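"""Windowed and whole-region p-distance computation.

p-distance is the uncorrected proportion of differing nucleotide sites
between two aligned sequences. Two deletion policies are supported:
``pairwise_deletion`` drops a column when either member of the pair is
gap/N/ambiguous; ``complete_deletion`` drops a column when *any* row of a
supplied context alignment is, so that all pairs in a distance matrix are
computed on the same column set (the convention used for NJ trees here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .alignio import Alignment, AlignmentError, Interval, MISSING_CODE, TaxonLabel

#: sentinel for a window with no usable sites (never reported as 0.0)
MISSING = None

PAIRWISE_DELETION = "pairwise_deletion"
COMPLETE_DELETION = "complete_deletion"


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: width, step, and minimum usable columns.

    A step equal to the width gives non-overlapping windows; the overlap
    quoted in figure legends is ``width - step`` (500-bp windows with a
    100-bp overlap -> step 400).
    """

    width: int
    step: int
    min_valid_sites: int | None = None

    def __post_init__(self):
        if self.width < 1:
            raise ValueError("width must be >= 1")
        if not (1 <= self.step <= self.width):
            raise ValueError("step must satisfy 1 <= step <= width")
        mvs = self.min_valid_sites
        if mvs is None:
            object.__setattr__(self, "min_valid_sites", max(1, self.width // 2))
        elif not (0 <= mvs <= self.width):
            raise ValueError("min_valid_sites must be in [0, width]")

    @classmethod
    def from_overlap(cls, width: int, overlap: int, min_valid_sites: int | None = None):
        return cls(width=width, step=width - overlap, min_valid_sites=min_valid_sites)


@dataclass
class DistanceProfile:
    """Per-window p-distances for one sequence pair (the profile object)."""

    pair: tuple[TaxonLabel, TaxonLabel]
    windows: list[tuple[Interval, float | None, int]] = field(default_factory=list)

    def to_rows(self):
        a, b = self.pair
        for iv, p, n in self.windows:
            yield (a, b, iv.start, iv.end, "NA" if p is None else f"{p:.6g}", n)


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix on one shared (complete-deletion) site set."""

    taxa: list[TaxonLabel]
    entries: np.ndarray
    sites_used: int

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=float)
        n = len(self.taxa)
        if self.entries.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.entries, self.entries.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.entries) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.entries < 0):
            raise ValueError("negative distances")


def iter_windows(length: int, spec: WindowSpec) -> list[Interval]:
    """Tile ``[0, length)`` with windows ``[k*step, k*step+width)``.

    Full windows are emitted while they fit; one final partial window is
    appended iff it spans at least ``min_valid_sites`` columns. A length
    below ``min_valid_sites`` yields an empty list.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    out: list[Interval] = []
    k = 0
    while k * spec.step + spec.width <= length:
        out.append(Interval(k * spec.step, k * spec.step + spec.width))
        k += 1
    start = k * spec.step
    if start < length and (length - start) >= spec.min_valid_sites:
        if not out or start > out[-1].start:
            out.append(Interval(start, length))
    return out


def pairwise_p_distance(
    a: str | np.ndarray,
    b: str | np.ndarray,
    interval: Interval | None = None,
    policy: str = PAIRWISE_DELETION,
    context: Alignment | None = None,
) -> tuple[float | None, int]:
    """p-distance between two rows over ``interval``.

    Returns ``(p, valid_sites)``; ``p`` is ``None`` (MISSING) when no column
    is usable. Under ``complete_deletion`` a context alignment must be given
    and a column is excluded when any of its rows is missing there.
    """
    ca = _coerce_codes(a)
    cb = _coerce_codes(b)
    if ca.shape != cb.shape:
        raise ValueError("rows differ in length")
    if interval is not None:
        if interval.end > ca.shape[0]:
            raise ValueError("interval exceeds row length")
        ca = ca[interval.start : interval.end]
        cb = cb[interval.start : interval.end]
    valid = (ca != MISSING_CODE) & (cb != MISSING_CODE)
    if policy == COMPLETE_DELETION:
        if context is None:
            raise ValueError("complete_deletion requires a context alignment")
        ctx = context.codes
        if interval is not None:
            ctx = ctx[:, interval.start : interval.end]
        valid &= np.all(ctx != MISSING_CODE, axis=0)
    elif policy != PAIRWISE_DELETION:
        raise ValueError(f"unknown deletion policy {policy!r}")
    n = int(valid.sum())
    if n == 0:
        return MISSING, 0
    mism = int(((ca != cb) & valid).sum())
    return mism / n, n


def _coerce_codes(row) -> np.ndarray:
    if isinstance(row, np.ndarray):
        return row
    from .alignio import BASE_CODES

    lut = np.full(256, MISSING_CODE, dtype=np.uint8)
    for base, code in BASE_CODES.items():
        lut[ord(base)] = code
    return lut[np.frombuffer(row.upper().encode("ascii"), dtype=np.uint8)]


def distance_profile(
    aln: Alignment,
    pair: tuple[TaxonLabel, TaxonLabel],
    spec: WindowSpec,
    policy: str = PAIRWISE_DELETION,
) -> DistanceProfile:
    """Windowed p-distance series for one taxon pair (the Fig-1-style track)."""
    ia, ib = aln.index_of(pair[0]), aln.index_of(pair[1])
    codes = aln.codes
    prof = DistanceProfile(pair=pair)
    for iv in iter_windows(aln.length, spec):
        p, n = pairwise_p_distance(
            codes[ia], codes[ib], iv, policy=policy, context=aln if policy == COMPLETE_DELETION else None
        )
        if n < spec.min_valid_sites:
            prof.windows.append((iv, MISSING, n))
        else:
            prof.windows.append((iv, p, n))
    return prof


def complete_columns(aln: Alignment, interval: Interval | None = None) -> np.ndarray:
    """Indices (within the interval) of columns with no missing cell in any row."""
    codes = aln.codes
    if interval is not None:
        codes = codes[:, interval.start : interval.end]
    return np.nonzero(np.all(codes != MISSING_CODE, axis=0))[0]


def distance_matrix(
    aln: Alignment,
    interval: Interval | None = None,
    policy: str = COMPLETE_DELETION,
    min_valid_sites: int = 1,
) -> DistanceMatrix:
    """All-pairs p-distance matrix on a shared column set.

    Under complete deletion (the default, as used for tree building) every
    column containing a gap/N/ambiguity in any row is removed before any
    pair is compared, so all entries rest on the same ``sites_used`` columns.
    """
    if len(aln) < 3:
        raise AlignmentError("distance_matrix needs >=3 taxa")
    codes = aln.codes
    if interval is not None:
        codes = codes[:, interval.start : interval.end]
    if policy == COMPLETE_DELETION:
        keep = np.all(codes != MISSING_CODE, axis=0)
        sub = codes[:, keep]
        n_sites = sub.shape[1]
        if n_sites < min_valid_sites:
            where = interval.human() if interval is not None else "whole alignment"
            raise AlignmentError(
                f"only {n_sites} complete columns in {where} (need {min_valid_sites})"
            )
        diff = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
        mat = diff / n_sites
        np.fill_diagonal(mat, 0.0)
        return DistanceMatrix(list(aln.taxa), mat, n_sites)
    if policy == PAIRWISE_DELETION:
        n = len(aln)
        mat = np.zeros((n, n))
        min_sites = None
        for i in range(n):
            for j in range(i + 1, n):
                valid = (codes[i] != MISSING_CODE) & (codes[j] != MISSING_CODE)
                cnt = int(valid.sum())
                min_sites = cnt if min_sites is None else min(min_sites, cnt)
                if cnt == 0:
                    raise AlignmentError(f"no shared sites for pair {aln.taxa[i]}, {aln.taxa[j]}")
                mat[i, j] = mat[j, i] = ((codes[i] != codes[j]) & valid).sum() / cnt
        if min_sites is not None and min_sites < min_valid_sites:
            raise AlignmentError(f"pair with only {min_sites} shared sites (need {min_valid_sites})")
        return DistanceMatrix(list(aln.taxa), mat, min_sites or 0)
    raise ValueError(f"unknown deletion policy {policy!r}")


# ---------------------------------------------------------------------------
# Writers


def profile_to_tsv(profile: DistanceProfile, path) -> None:
    from .alignio import write_tsv

    write_tsv(path, ("taxon_a", "taxon_b", "start", "end", "p", "valid_sites"), profile.to_rows())


def profile_to_bedgraph(profile: DistanceProfile, path, name: str = "region") -> None:
    with open(path, "w") as fh:
        a, b = profile.pair
        fh.write(f'track type=bedGraph name="p {a} vs {b}"\n')
        for iv, p, _ in profile.windows:
            if p is not None:
                fh.write(f"{name}\t{iv.start}\t{iv.end}\t{p:.6g}\n")
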