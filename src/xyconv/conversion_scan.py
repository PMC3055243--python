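"""Sliding-tree conversion scan: segment, map events, orient, localize.

The pipeline slides NJ trees across the alignment, classifies each window
(reciprocal monophyly vs species pairing), merges runs of identical
signature into sub-regions, places the minimal set of conversion events on
the species tree per sub-region, polarizes each event with an outgroup, and
can localize a single topology switch to the column.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .alignio import Alignment, Interval, SpeciesTree, TaxonLabel, MISSING_CODE
from .distances import (
    WindowSpec,
    complete_columns,
    distance_matrix,
    iter_windows,
    pairwise_p_distance,
)
from .njphylo import (
    MIXED,
    RECIPROCAL_MONOPHYLY,
    SPECIES_PAIRING,
    UNRESOLVED,
    DEFAULT_SUPPORT_THRESHOLD,
    PhyloTree,
    TopologyCall,
    _canon,
    _matrix_from_pair_values,
    _pair_mismatch_matrix,
    bootstrap_tree,
    classify_topology,
    nj_bipartition_masks,
    nj_tree,
)

log = logging.getLogger(__name__)

X_TO_Y = "X_TO_Y"
Y_TO_X = "Y_TO_X"
UNKNOWN = "UNKNOWN"

DEFAULT_NESTING_FACTOR = 0.5
DEFAULT_MIN_VOTES = 3


@dataclass
class SubRegion:
    """A maximal run of windows sharing one topology signature."""

    interval: Interval
    signature: TopologyCall
    n_windows: int


@dataclass
class ConversionEvent:
    """A single inferred X-Y gene conversion.

    ``branch`` is the species-tree edge carrying the event, identified by
    its descendant species set; ``t_low``/``t_high`` bound the event time in
    myr (initially the branch's existence interval, refined by dating).
    """

    branch: frozenset
    interval: Interval
    direction: str = UNKNOWN
    t_low: float | None = None
    t_high: float | None = None
    evidence: tuple = ()
    votes: tuple[int, int] = (0, 0)  # (Y->X, X->Y) informative sites
    se_low: float | None = None
    se_high: float | None = None

    def branch_name(self) -> str:
        return "+".join(sorted(self.branch))


@dataclass
class Breakpoint:
    """Column estimate of a topology switch inside an interval."""

    column: int
    left_call: TopologyCall
    right_call: TopologyCall
    score: float
    no_switch: bool = False


# ---------------------------------------------------------------------------
# Scan + segmentation


def scan_topologies(
    aln: Alignment,
    spec: WindowSpec,
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
    n_reps: int = 100,
    seed: int | np.random.Generator = 0,
) -> list[tuple[Interval, TopologyCall]]:
    """One bootstrap NJ tree and topology call per sliding window.

    Windows with fewer complete columns than ``spec.min_valid_sites`` are
    emitted as UNRESOLVED rather than skipped, so the window grid stays
    regular for segmentation.
    """
    if len(aln.xy_species()) < 2:
        raise ValueError("scan needs >=2 species with both X and Y sequences")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for iv in iter_windows(aln.length, spec):
        n_complete = complete_columns(aln, iv).size
        if n_complete < spec.min_valid_sites:
            out.append(
                (iv, TopologyCall(UNRESOLVED, support_ok=False, reason="too few complete sites"))
            )
            continue
        tree = bootstrap_tree(aln, iv, n_reps=n_reps, seed=rng)
        out.append((iv, classify_topology(tree, support_threshold)))
    return out


def segment_subregions(
    calls: list[tuple[Interval, TopologyCall]]
) -> list[SubRegion]:
    """Merge runs of identical signature into ordered, non-overlapping
    sub-regions covering the classified extent.

    Boundaries between differing neighbors sit at the midpoint of their
    window overlap; UNRESOLVED runs are absorbed into the flanking run with
    which they share more columns (ties to the left) and flanks that then
    agree are merged.
    """
    if not calls:
        return []
    sigs = [c.signature() for _, c in calls]
    unresolved = [s[0] == UNRESOLVED for s in sigs]
    if all(unresolved):
        log.warning("all windows UNRESOLVED; no sub-regions")
        return []

    # absorb unresolved runs
    resolved_sig = list(sigs)
    i = 0
    while i < len(calls):
        if not unresolved[i]:
            i += 1
            continue
        j = i
        while j < len(calls) and unresolved[j]:
            j += 1
        left = i - 1
        right = j if j < len(calls) else None
        if left < 0 and right is None:
            break
        if left < 0:
            take = right
        elif right is None:
            take = left
        else:
            run_iv = Interval(calls[i][0].start, calls[j - 1][0].end)
            left_share = max(0, calls[left][0].end - run_iv.start)
            right_share = max(0, run_iv.end - calls[right][0].start)
            take = left if left_share >= right_share else right
        for k in range(i, j):
            resolved_sig[k] = sigs[take]
        i = j

    # pick a representative call for each signature
    rep: dict = {}
    for (iv, call), s in zip(calls, resolved_sig):
        rep.setdefault(s, call)

    regions: list[SubRegion] = []
    run_start = 0
    for k in range(1, len(calls) + 1):
        if k == len(calls) or resolved_sig[k] != resolved_sig[run_start]:
            first_iv = calls[run_start][0]
            last_iv = calls[k - 1][0]
            start = first_iv.start if run_start == 0 else _boundary(calls[run_start - 1][0], first_iv)
            end = last_iv.end if k == len(calls) else _boundary(last_iv, calls[k][0])
            regions.append(
                SubRegion(Interval(start, end), rep[resolved_sig[run_start]], k - run_start)
            )
            run_start = k
    return regions


def _boundary(left: Interval, right: Interval) -> int:
    """Midpoint of the overlap (or gap) between two adjacent windows."""
    return (right.start + left.end) // 2


# ---------------------------------------------------------------------------
# Event mapping


def _minimal_branch_cover(group: frozenset, species_tree: SpeciesTree) -> list[frozenset]:
    """Minimal set of species-tree branches whose descendant sets exactly
    cover ``group``.

    Candidate branches have descendant sets inside the group (an event on a
    branch implies pairing in *all* its descendants, so no non-group species
    may descend from a chosen branch). Branch descendant sets are laminar,
    hence the maximal candidates form the unique minimum cover.
    """
    missing = group - set(species_tree.species)
    if missing:
        raise ValueError(f"paired species absent from species tree: {sorted(missing)}")
    cands = [b for b in species_tree.branches() if b <= group]
    maximal = [b for b in cands if not any(b < other for other in cands)]
    covered = frozenset().union(*maximal) if maximal else frozenset()
    if covered != group:
        raise ValueError(f"species {sorted(group - covered)} not coverable on the tree")
    return sorted(maximal, key=lambda b: (len(b), sorted(b)))


def _species_xy_p(aln: Alignment, species: str, interval: Interval) -> float | None:
    """Mean X-Y p-distance within one species over an interval."""
    xs = aln.taxa_for(species, "X")
    ys = aln.taxa_for(species, "Y")
    vals = []
    for tx in xs:
        for ty in ys:
            p, n = pairwise_p_distance(
                aln.codes[aln.index_of(tx)], aln.codes[aln.index_of(ty)], interval
            )
            if p is not None:
                vals.append(p)
    return float(np.mean(vals)) if vals else None


def map_events(
    subregions: list[SubRegion],
    species_tree: SpeciesTree,
    aln: Alignment | None = None,
    nesting_factor: float = DEFAULT_NESTING_FACTOR,
) -> list[ConversionEvent]:
    """Place the minimal number of conversion events per sub-region.

    Each detected group maps to the minimal branch cover of its species set.
    Within a multi-species group explained by one ancestral event, a member
    whose own X-Y divergence is below ``nesting_factor`` times the median of
    the other members' receives an additional, more recent event on its
    terminal branch (a conversion-on-conversion).
    Events in adjacent sub-regions on the same branch are deliberately not
    merged; each sub-region is evidence for its own event.
    """
    branches = species_tree.branches()
    events: list[ConversionEvent] = []
    for ridx, sr in enumerate(subregions):
        groups = list(sr.signature.paired_groups)
        own_group_species = {s for g in groups if len(g) == 1 for s in g}
        for group in groups:
            for branch in _minimal_branch_cover(group, species_tree):
                t0, t1 = branches[branch]
                events.append(
                    ConversionEvent(
                        branch=branch,
                        interval=sr.interval,
                        t_low=t0,
                        t_high=t1,
                        evidence=(ridx, sr.n_windows),
                    )
                )
            # nested more-recent events inside an ancestral group
            if len(group) >= 2 and aln is not None:
                pvals = {s: _species_xy_p(aln, s, sr.interval) for s in group}
                for s in sorted(group):
                    if s in own_group_species:
                        continue
                    others = [
                        pvals[t]
                        for t in group
                        if t != s and t not in own_group_species and pvals[t] is not None
                    ]
                    if pvals[s] is None or not others:
                        continue
                    if pvals[s] < nesting_factor * float(np.median(others)):
                        t0, t1 = branches[frozenset([s])]
                        events.append(
                            ConversionEvent(
                                branch=frozenset([s]),
                                interval=sr.interval,
                                t_low=t0,
                                t_high=t1,
                                evidence=(ridx, sr.n_windows),
                            )
                        )
    return events


# ---------------------------------------------------------------------------
# Direction inference


def default_outgroup_taxa(aln: Alignment) -> list[TaxonLabel]:
    """Outgroup default: any taxon of a species lacking X or Y (e.g. a New
    World monkey or prosimian X sequence outside the stratum)."""
    xy = set(aln.xy_species())
    return [t for t in aln.taxa if t.species not in xy]


@dataclass(frozen=True)
class DirectionCall:
    direction: str
    n_y_to_x: int
    n_x_to_y: int


def infer_direction(
    aln: Alignment,
    event: ConversionEvent,
    outgroup_taxa: list[TaxonLabel] | None = None,
    interval: Interval | None = None,
    min_votes: int = DEFAULT_MIN_VOTES,
    exclude_species: frozenset = frozenset(),
) -> DirectionCall:
    """Polarize one event using sites where unconverted relatives' X and Y
    states differ and an outgroup fixes the ancestral state.

    At such a site the non-ancestral state is a derived substitution on the
    X or the Y lineage; if the converted species' X *and* Y both carry the
    Y-derived state the site votes Y->X, and symmetrically for X->Y. The
    call requires ``min_votes`` informative sites and a strict majority.
    """
    if outgroup_taxa is None:
        outgroup_taxa = default_outgroup_taxa(aln)
    if not outgroup_taxa:
        raise ValueError("direction inference needs at least one outgroup sequence")
    iv = interval or event.interval
    conv = set(event.branch)
    ref_species = [
        s
        for s in aln.xy_species()
        if s not in conv and s not in exclude_species
    ]
    codes = aln.codes[:, iv.start : iv.end]

    def group_state(taxa) -> np.ndarray:
        rows = codes[[aln.index_of(t) for t in taxa]]
        first = rows[0]
        same = np.all(rows == first, axis=0) & (first != MISSING_CODE)
        out = np.where(same, first, MISSING_CODE).astype(np.uint8)
        return out

    ref_x = group_state([t for s in ref_species for t in aln.taxa_for(s, "X")])
    ref_y = group_state([t for s in ref_species for t in aln.taxa_for(s, "Y")])
    out_state = group_state(outgroup_taxa)
    conv_taxa = [
        t for s in conv for t in aln.taxa_for(s) if t.chromosome in ("X", "Y")
    ]
    conv_state = group_state(conv_taxa)

    usable = (
        (ref_x != MISSING_CODE)
        & (ref_y != MISSING_CODE)
        & (ref_x != ref_y)
        & (out_state != MISSING_CODE)
        & (conv_state != MISSING_CODE)
    )
    anc_is_x = usable & (out_state == ref_x)
    anc_is_y = usable & (out_state == ref_y)
    votes_y2x = int(np.sum(anc_is_x & (conv_state == ref_y)))
    votes_x2y = int(np.sum(anc_is_y & (conv_state == ref_x)))
    total = votes_y2x + votes_x2y
    if total >= min_votes and votes_y2x != votes_x2y:
        direction = Y_TO_X if votes_y2x > votes_x2y else X_TO_Y
    else:
        direction = UNKNOWN
    return DirectionCall(direction, votes_y2x, votes_x2y)


# ---------------------------------------------------------------------------
# Breakpoint localization


def locate_breakpoint(
    aln: Alignment,
    interval: Interval,
    candidate_step: int = 1,
    n_boot: int = 100,
    seed: int | np.random.Generator = 0,
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
    min_seg_sites: int = 25,
    flank: int = 600,
) -> Breakpoint:
    """Localize a single reciprocal-monophyly / species-pairing switch.

    For each candidate column c the score is the bootstrap support of the
    X|Y-separating edge on the columns just left of c plus the mean support
    of the pairing clades on the columns just right of c (each side capped
    at ``flank`` columns — the score must be local to c, otherwise whichever
    pattern dominates the whole interval saturates both sides and the
    profile loses its peak); the argmax (ties to the smallest c) is
    returned. A flat profile (max - min < 5 support points) sets the
    no-switch flag.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = complete_columns(aln, interval)
    codes = aln.codes[:, interval.start : interval.end][:, cols]
    n = len(aln)
    M, pairs = _pair_mismatch_matrix(codes)
    full = (1 << n) - 1

    # targets: RM bipartition(s) from labels; pairing clades from the right flank
    xy = aln.xy_species()
    x_mask = sum(1 << i for i, t in enumerate(aln.taxa) if t.chromosome == "X" and t.species in xy)
    y_mask = sum(1 << i for i, t in enumerate(aln.taxa) if t.chromosome == "Y" and t.species in xy)
    rm_targets = {_canon(x_mask, full), _canon(y_mask, full)}

    lo = max(interval.start, interval.end - flank)
    right_tree = bootstrap_tree(aln, Interval(lo, interval.end), n_reps=n_boot, seed=rng)
    right_call = classify_topology(right_tree, support_threshold)
    pair_groups = right_call.paired_groups or tuple(frozenset([s]) for s in xy)
    pair_targets = set()
    for g in pair_groups:
        m = sum(1 << i for i, t in enumerate(aln.taxa) if t.species in g)
        pair_targets.add(_canon(m, full))

    def side_support(col_mask: np.ndarray, targets: set[int]) -> float:
        idx = np.nonzero(col_mask)[0]
        m = idx.size
        if m < min_seg_sites or not targets:
            return 0.0
        Msub = M[:, idx]
        hits = 0
        p = np.full(m, 1.0 / m)
        for _ in range(n_boot):
            w = rng.multinomial(m, p)
            vals = (Msub @ w) / m
            D = _matrix_from_pair_values(vals, pairs, n)
            masks = nj_bipartition_masks(D)
            hits += sum(1 for t in targets if t in masks) / len(targets)
        return 100.0 * hits / n_boot

    candidates = list(range(interval.start, interval.end + 1, candidate_step))
    if candidates[-1] != interval.end:
        candidates.append(interval.end)
    abs_cols = cols + interval.start
    scores, interior = [], []
    for c in candidates:
        left = (abs_cols < c) & (abs_cols >= c - flank)
        right = (abs_cols >= c) & (abs_cols < c + flank)
        scores.append(side_support(left, rm_targets) + side_support(right, pair_targets))
        interior.append(left.sum() >= min_seg_sites and right.sum() >= min_seg_sites)
    scores = np.asarray(scores)
    interior = np.asarray(interior)
    if not interior.any():
        interior[:] = True
    smax = scores[interior].max()
    left_tree = bootstrap_tree(
        aln,
        Interval(interval.start, min(interval.end, interval.start + flank)),
        n_reps=n_boot,
        seed=rng,
    )
    left_call = classify_topology(left_tree, support_threshold)
    # no switch when the two end flanks show the same signature, or the
    # score profile is flat over interior candidates (edge candidates with
    # a truncated side score 0 by construction and are excluded)
    no_switch = bool(
        left_call.signature() == right_call.signature()
        or smax - scores[interior].min() < 5.0
    )
    if no_switch:
        col = candidates[0]
    else:
        # both supports saturate near the switch, so the maximum is a
        # plateau roughly symmetric about the boundary: take its midpoint
        # (plateau = contiguous near-max run around the argmax; exact ties
        # resolve to the smallest candidate)
        plateau_tol = 5.0
        idx = [i for i in range(len(candidates)) if interior[i]]
        first = min(i for i in idx if scores[i] >= smax - 1e-9)
        lo = hi = first
        while lo - 1 in idx and scores[lo - 1] >= smax - plateau_tol:
            lo -= 1
        while hi + 1 in idx and scores[hi + 1] >= smax - plateau_tol:
            hi += 1
        col = candidates[(lo + hi) // 2]
    return Breakpoint(
        column=col,
        left_call=left_call,
        right_call=right_call,
        score=0.0 if no_switch else float(smax),
        no_switch=no_switch,
    )


# ---------------------------------------------------------------------------
# Writers


def calls_to_tsv(calls, path):
    from .alignio import write_tsv

    rows = [
        (
            iv.start,
            iv.end,
            call.call,
            ";".join("+".join(sorted(g)) for g in call.paired_groups),
            int(call.support_ok),
        )
        for iv, call in calls
    ]
    write_tsv(path, ("start", "end", "call", "paired_groups", "support_ok"), rows)


def subregions_to_bed(subregions, path, name="region"):
    from .alignio import write_bed

    rows = [
        (
            name,
            sr.interval.start,
            sr.interval.end,
            f"{sr.signature.call}:{';'.join('+'.join(sorted(g)) for g in sr.signature.paired_groups)}",
            sr.n_windows,
        )
        for sr in subregions
    ]
    write_bed(path, rows)


def events_to_tsv(events, path):
    from .alignio import write_tsv

    rows = [
        (
            i,
            ev.branch_name(),
            ev.interval.start,
            ev.interval.end,
            ev.direction,
            "NA" if ev.t_low is None else f"{ev.t_low:.3g}",
            "NA" if ev.t_high is None else f"{ev.t_high:.3g}",
            ev.votes[0],
            ev.votes[1],
            f"subregion={ev.evidence[0]};windows={ev.evidence[1]}" if ev.evidence else "",
        )
        for i, ev in enumerate(events)
    ]
    write_tsv(
        path,
        (
            "event_id",
            "branch",
            "start",
            "end",
            "direction",
            "t_low_myr",
            "t_high_myr",
            "votes_y_to_x",
            "votes_x_to_y",
            "evidence",
        ),
        rows,
    )


def events_to_bed(events, path, name="region"):
    from .alignio import write_bed

    rows = [
        (
            name,
            ev.interval.start,
            ev.interval.end,
            f"{ev.branch_name()}|{ev.direction}",
            min(1000, ev.evidence[1] * 100 if ev.evidence else 0),
            ".",
            ev.interval.start,
            ev.interval.end,
            "0,0,0",
        )
        for ev in events
    ]
    write_bed(path, rows)
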