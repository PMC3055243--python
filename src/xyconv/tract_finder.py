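"""Short recent conversion tracts as anomalous identical runs.

A very recent X-Y conversion leaves one allele carrying a perfect copy of
the donor over a short tract, against a backdrop of fixed X-Y differences.
The signal is a maximal gap-free run where a focal X allele is identical to
a Y allele *and* the run contains diagnostic sites — columns where all other
X alleles share one state and all Y alleles share another — at which the
focal allele carries the Y state. The null (all diagnostic sites converged
independently by recurrent substitution) gives
``p = per_site_match_prob ** n_diagnostic``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alignio import Alignment, Interval, MISSING_CODE, TaxonLabel
from .distances import pairwise_p_distance

log = logging.getLogger(__name__)

DEFAULT_MIN_TRACT = 50


@dataclass
class TractHit:
    """One candidate conversion tract between a focal X allele and a Y allele."""

    interval: Interval
    x_allele: TaxonLabel
    y_allele: TaxonLabel
    run_length_bp: int
    n_diagnostic: int | None
    p_value: float | None
    unpolarized: bool = False  # True when no other X allele was available


def diagnostic_sites(
    aln: Alignment,
    x_group: list[TaxonLabel],
    y_group: list[TaxonLabel],
    interval: Interval | None = None,
) -> list[int]:
    """Columns with a fixed, unambiguous X/Y difference.

    A column qualifies iff all ``x_group`` rows share one ACGT state, all
    ``y_group`` rows share another, and the two differ; any gap/N/ambiguity
    in either group disqualifies the column. Returned coordinates are
    absolute (alignment columns).
    """
    if not x_group or not y_group:
        return []
    codes = aln.codes
    lo = interval.start if interval else 0
    hi = interval.end if interval else aln.length
    xs = codes[[aln.index_of(t) for t in x_group], lo:hi]
    ys = codes[[aln.index_of(t) for t in y_group], lo:hi]
    x_uni = np.all(xs == xs[0], axis=0) & (xs[0] != MISSING_CODE)
    y_uni = np.all(ys == ys[0], axis=0) & (ys[0] != MISSING_CODE)
    ok = x_uni & y_uni & (xs[0] != ys[0])
    return [int(c) + lo for c in np.nonzero(ok)[0]]


def recurrent_substitution_pvalue(
    n_diagnostic: int, tract_span: int, per_site_match_prob: float
) -> float:
    """Probability that every diagnostic site matched the donor state by
    independent recurrent substitution. ``tract_span`` is carried for the
    record; the independence null depends only on the site count."""
    if n_diagnostic < 0:
        raise ValueError("n_diagnostic must be >= 0")
    if not (0.0 < per_site_match_prob < 1.0):
        raise ValueError("per_site_match_prob must be in (0, 1)")
    if n_diagnostic == 0:
        return 1.0
    return float(per_site_match_prob**n_diagnostic)


def find_identical_tracts(
    aln: Alignment,
    focal_x: TaxonLabel,
    y_allele: TaxonLabel,
    min_tract: int = DEFAULT_MIN_TRACT,
    per_site_match_prob: float | None = None,
) -> list[TractHit]:
    """Maximal identical runs between a focal X allele and a Y allele.

    Gaps (and any non-ACGT state) break runs. A run is reported iff it is at
    least ``min_tract`` columns long and contains >=1 diagnostic site at
    which the focal allele carries the Y state (identity alone cannot be
    told apart from chance). With no other X allele present, hits are
    reported unpolarized with ``n_diagnostic``/``p_value`` unset.

    ``per_site_match_prob`` defaults to the focal-vs-Y p-distance outside
    the run divided by 3 (the chance a random substitution lands on the
    donor state).
    """
    fi = aln.index_of(focal_x)
    yi = aln.index_of(y_allele)
    codes = aln.codes
    other_x = [
        t
        for t in aln.taxa
        if t.chromosome == "X" and t != focal_x and t.species == focal_x.species
    ]
    y_group = [t for t in aln.taxa if t.chromosome == "Y" and t.species == y_allele.species]
    if not other_x:
        log.warning("no other X allele for polarization; hits reported unpolarized")

    match = (
        (codes[fi] == codes[yi])
        & (codes[fi] != MISSING_CODE)
        & (codes[yi] != MISSING_CODE)
    )
    diag = set(diagnostic_sites(aln, other_x, y_group)) if other_x else set()

    hits: list[TractHit] = []
    L = aln.length
    c = 0
    while c < L:
        if not match[c]:
            c += 1
            continue
        start = c
        while c < L and match[c]:
            c += 1
        end = c
        run_len = end - start
        if run_len < min_tract:
            continue
        iv = Interval(start, end)
        if not other_x:
            hits.append(
                TractHit(iv, focal_x, y_allele, run_len, None, None, unpolarized=True)
            )
            continue
        n_diag = sum(1 for s in diag if start <= s < end)
        if n_diag == 0:
            continue
        prob = per_site_match_prob
        if prob is None:
            outside = np.ones(L, dtype=bool)
            outside[start:end] = False
            fa = np.where(outside, codes[fi], MISSING_CODE).astype(np.uint8)
            p_out, n_out = pairwise_p_distance(fa, codes[yi])
            prob = (p_out / 3.0) if (p_out is not None and p_out > 0) else None
        if prob is None or prob <= 0:
            p_val = None
        else:
            p_val = recurrent_substitution_pvalue(n_diag, run_len, min(prob, 0.999999))
        hits.append(TractHit(iv, focal_x, y_allele, run_len, n_diag, p_val))
    return hits


def tracts_to_tsv(hits: list[TractHit], path) -> None:
    from .alignio import write_tsv

    rows = [
        (
            h.x_allele,
            h.y_allele,
            h.interval.start,
            h.interval.end,
            h.run_length_bp,
            "NA" if h.n_diagnostic is None else h.n_diagnostic,
            "NA" if h.p_value is None else f"{h.p_value:.3g}",
            int(h.unpolarized),
        )
        for h in hits
    ]
    write_tsv(
        path,
        ("x_allele", "y_allele", "start", "end", "run_length_bp", "n_diagnostic", "p_value", "unpolarized"),
        rows,
    )


def tracts_to_bed(hits: list[TractHit], path, name="region") -> None:
    from .alignio import write_bed

    write_bed(
        path,
        [
            (name, h.interval.start, h.interval.end, f"{h.x_allele}<-{h.y_allele}")
            for h in hits
        ],
    )
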