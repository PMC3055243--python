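"""Branch-specific divergence, calibrated substitution rates, event dating.

X- and Y-linked sequences accumulate substitutions at different rates (male
mutation bias), so per-site divergence d is estimated separately on the
branches leading to the X tips (d_X) and the Y tips (d_Y) from a calibrated
split. Dividing by the calibration time gives absolute rates r_X, r_Y; the
X-Y coalescence depth of a converted clade, divided by those rates, brackets
the conversion time. All times are myr; rates are substitutions/site/year;
the myr-to-year factor is centralized in :data:`YEARS_PER_MYR`.

Standard errors are site-bootstrap (columns resampled with replacement, the
tree rebuilt, the quantity recomputed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alignio import Alignment, Interval, SpeciesTree
from .distances import complete_columns, distance_matrix, DistanceMatrix
from .njphylo import PhyloTree, _matrix_from_pair_values, _pair_mismatch_matrix, nj_tree

log = logging.getLogger(__name__)

YEARS_PER_MYR = 1.0e6
DEFAULT_BOOTSTRAP_REPS = 200


class DatingError(ValueError):
    pass


@dataclass
class LineageDivergence:
    """Mean per-site divergence from a calibration split to X and Y tips."""

    d_X: float
    d_Y: float
    se_X: float
    se_Y: float

    def __post_init__(self):
        if self.d_X < 0 or self.d_Y < 0 or self.se_X < 0 or self.se_Y < 0:
            raise ValueError("divergences and standard errors must be >= 0")


@dataclass
class RateEstimates:
    """Absolute substitution rates from a fossil-calibrated split."""

    r_X: float
    r_Y: float
    se_rX: float
    se_rY: float
    calibration_time_myr: float

    def __post_init__(self):
        if self.r_X < 0 or self.r_Y < 0:
            raise ValueError("rates must be >= 0")


def _divergence_from_tree(
    tree: PhyloTree, split_species: tuple, chromosome: str
) -> float:
    """d for one chromosome: mean path from the calibration-split node
    (within that chromosome's clade) to each of that chromosome's tips.

    Raises :class:`DatingError` when the chromosome's leaves are not
    monophyletic (dating is only meaningful on unconverted, or uniformly
    converted, regions).
    """
    side_a, side_b = (set(s) for s in split_species)
    species = side_a | side_b
    chrom_mask = tree.leaf_mask(lambda t: t.chromosome == chromosome)
    if chrom_mask == 0:
        raise DatingError(f"no chromosome-{chromosome} leaves in tree")
    target_mask = tree.leaf_mask(
        lambda t: t.chromosome == chromosome and t.species in species
    )
    try:
        tree.clade_anchor(chrom_mask)
    except ValueError:
        raise DatingError(
            f"chromosome {chromosome} leaves are not monophyletic; "
            "region looks converted or unresolved"
        ) from None
    node = tree.mrca_in_clade(chrom_mask, target_mask)
    return tree.mean_path_from(node, target_mask)


def lineage_divergence(
    aln: Alignment,
    calibration_split: tuple,
    chromosome: str,
    interval: Interval | None = None,
    n_boot: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """(d, se) for one chromosome from the NJ tree of the region.

    ``calibration_split`` is a pair of species collections, e.g.
    ``({"rhesus"}, {"human", "chimp"})`` for the rhesus-hominoid split.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dm = distance_matrix(aln, interval)
    tree = nj_tree(dm)
    d = _divergence_from_tree(tree, calibration_split, chromosome)

    cols = complete_columns(aln, interval)
    codes = aln.codes if interval is None else aln.codes[:, interval.start : interval.end]
    sub = codes[:, cols]
    M, pairs = _pair_mismatch_matrix(sub)
    m = sub.shape[1]
    p = np.full(m, 1.0 / m)
    reps = []
    failed = 0
    for _ in range(n_boot):
        w = rng.multinomial(m, p)
        vals = (M @ w) / m
        D = _matrix_from_pair_values(vals, pairs, len(aln.taxa))
        btree = PhyloTree.from_distance_matrix(DistanceMatrix(list(aln.taxa), D, m))
        try:
            reps.append(_divergence_from_tree(btree, calibration_split, chromosome))
        except DatingError:
            failed += 1
    if failed:
        log.info("%d/%d bootstrap replicates lost the chromosome clade", failed, n_boot)
    se = float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0
    return d, se


def lineage_divergence_xy(
    aln: Alignment,
    calibration_split: tuple,
    interval: Interval | None = None,
    n_boot: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int = 0,
) -> LineageDivergence:
    rng = np.random.default_rng(seed)
    d_x, se_x = lineage_divergence(aln, calibration_split, "X", interval, n_boot, rng)
    d_y, se_y = lineage_divergence(aln, calibration_split, "Y", interval, n_boot, rng)
    return LineageDivergence(d_X=d_x, d_Y=d_y, se_X=se_x, se_Y=se_y)


def substitution_rates(div: LineageDivergence, T_myr: float) -> RateEstimates:
    """Convert divergences into substitutions/site/year given a split age.

    r = d / (T * 1e6); the standard error propagates linearly.
    """
    if T_myr <= 0:
        raise ValueError("calibration time must be positive")
    denom = T_myr * YEARS_PER_MYR
    return RateEstimates(
        r_X=div.d_X / denom,
        r_Y=div.d_Y / denom,
        se_rX=div.se_X / denom,
        se_rY=div.se_Y / denom,
        calibration_time_myr=T_myr,
    )


@dataclass
class DatedConversion:
    t_low: float
    t_high: float
    se_low: float
    se_high: float
    clipped: bool = False


def _coalescence_depths(tree: PhyloTree, species: frozenset) -> tuple[float, float]:
    """(b_X, b_Y): mean path from the X-Y coalescent node of the converted
    clade to its X tips and to its Y tips."""
    clade_mask = tree.leaf_mask(
        lambda t: t.species in species and t.chromosome in ("X", "Y")
    )
    x_mask = tree.leaf_mask(lambda t: t.species in species and t.chromosome == "X")
    y_mask = tree.leaf_mask(lambda t: t.species in species and t.chromosome == "Y")
    if not x_mask or not y_mask:
        raise DatingError(f"species {sorted(species)} lack X or Y leaves")
    try:
        node = tree.clade_anchor(clade_mask)
    except ValueError:
        raise DatingError(
            f"X and Y of {sorted(species)} are not sister in this tree; "
            "no single conversion to date"
        ) from None
    return tree.mean_path_from(node, x_mask), tree.mean_path_from(node, y_mask)


def date_conversion(
    event,
    window_tree: PhyloTree,
    rates: RateEstimates,
    aln: Alignment | None = None,
    interval: Interval | None = None,
    n_boot: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int | np.random.Generator = 0,
    species_tree: SpeciesTree | None = None,
) -> DatedConversion:
    """Bracket an event's age from the X-Y coalescence depth of its clade.

    t_X = b_X / r_X and t_Y = b_Y / r_Y (in myr) are two estimates of the
    same conversion time from the two chromosome-specific clocks; their
    min/max is returned as (t_low, t_high), clipped to the carrying branch's
    existence interval when a species tree is given.
    """
    if rates.r_X <= 0 or rates.r_Y <= 0:
        raise DatingError("rates must be positive to date an event")
    b_x, b_y = _coalescence_depths(window_tree, event.branch)
    t_x = b_x / rates.r_X / YEARS_PER_MYR
    t_y = b_y / rates.r_Y / YEARS_PER_MYR
    t_low, t_high = min(t_x, t_y), max(t_x, t_y)

    se_low = se_high = 0.0
    if aln is not None and n_boot > 1:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        iv = interval or event.interval
        cols = complete_columns(aln, iv)
        codes = aln.codes[:, iv.start : iv.end][:, cols]
        M, pairs = _pair_mismatch_matrix(codes)
        m = codes.shape[1]
        p = np.full(m, 1.0 / m)
        lows, highs = [], []
        for _ in range(n_boot):
            w = rng.multinomial(m, p)
            vals = (M @ w) / m
            D = _matrix_from_pair_values(vals, pairs, len(aln.taxa))
            btree = PhyloTree.from_distance_matrix(DistanceMatrix(list(aln.taxa), D, m))
            try:
                bb_x, bb_y = _coalescence_depths(btree, event.branch)
            except DatingError:
                continue
            bt_x = bb_x / rates.r_X / YEARS_PER_MYR
            bt_y = bb_y / rates.r_Y / YEARS_PER_MYR
            lows.append(min(bt_x, bt_y))
            highs.append(max(bt_x, bt_y))
        if len(lows) > 1:
            se_low = float(np.std(lows, ddof=1))
            se_high = float(np.std(highs, ddof=1))

    clipped = False
    if species_tree is not None:
        _, parent_age = species_tree.branches().get(event.branch, (0.0, None))
        if parent_age is not None and t_high > parent_age:
            log.info(
                "event on %s dated %.2f myr, clipped to parent age %.2f",
                "+".join(sorted(event.branch)), t_high, parent_age,
            )
            t_high = parent_age
            t_low = min(t_low, t_high)
            clipped = True
    if t_low < 0:
        t_low, clipped = 0.0, True
    return DatedConversion(t_low, t_high, se_low, se_high, clipped)
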