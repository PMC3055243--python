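"""Forward simulator of gametolog evolution with a truth ledger.

The model: a single ancestral sequence evolves along a time-calibrated
species tree under Jukes-Cantor substitution. At ``stratum_age_myr``
(recombination arrest) each lineage's sequence forks into an X and a Y copy
that thereafter evolve at chromosome-specific rates r_X and r_Y
(substitutions/site/year). Scheduled gene conversions copy the donor tract
over the recipient instantaneously on a stated lineage at a stated time;
scheduled deletions replace an interval with gaps and are inherited. Allele
pairs within a species are approximated by evolving each sampled allele an
extra Exp(theta / 2r) years.

Branches are evolved with the exact JC transition kernel
``P(change) = (3/4)(1 - exp(-(4/3) r t))`` so that the expected X-Y
p-distance at stratum age T is ``(3/4)(1 - exp(-(4/3)(r_X + r_Y) T))`` in
closed form — about 0.10 for the stratum-4 backdrop (r_X + r_Y ~= 2.23e-9,
T ~= 47 myr). Everything is reproducible from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .alignio import Alignment, Interval, SpeciesTree, TaxonLabel, read_species_tree
from .conversion_scan import UNKNOWN, X_TO_Y, Y_TO_X

log = logging.getLogger(__name__)

GAP_CODE = 4
_DECODE = np.frombuffer(b"ACGT-", dtype=np.uint8)
YEARS_PER_MYR = 1.0e6

#: the default study system: a catarrhine tree (tip ages in myr) plus a New
#: World monkey whose X-only sequence serves as outgroup, with stratum-4
#: recombination arrest predating the root.
PRIMATE_NEWICK = "(nwm:40,(rhesus:30,(gibbon:18,(gorilla:8,(human:6,chimp:6):2):10):12):10);"
DEFAULT_STRATUM_AGE = 47.0
DEFAULT_R_X = 0.78e-9
DEFAULT_R_Y = 1.45e-9

FIXTURE_NAMES = (
    "fig1_profile",
    "fig3_ten_events",
    "fig4_gibbon",
    "fig5_breakpoint",
    "regionA_null",
)


class SimError(ValueError):
    pass


@dataclass(frozen=True)
class ConversionSpec:
    """A scheduled conversion: lineage (descendant species set), time (myr),
    tract [start, end), and direction (which chromosome is the donor)."""

    lineage: frozenset
    time_myr: float
    start: int
    end: int
    direction: str

    def __post_init__(self):
        object.__setattr__(self, "lineage", _as_lineage(self.lineage))
        if self.direction not in (X_TO_Y, Y_TO_X):
            raise SimError(f"direction must be {X_TO_Y} or {Y_TO_X}")
        if not (0 <= self.start < self.end):
            raise SimError("bad tract interval")


@dataclass(frozen=True)
class DeletionSpec:
    lineage: frozenset
    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        object.__setattr__(self, "lineage", _as_lineage(self.lineage))
        if self.chromosome not in ("X", "Y"):
            raise SimError("deletion chromosome must be X or Y")


def _as_lineage(val) -> frozenset:
    if isinstance(val, str):
        return frozenset([val])
    return frozenset(val)


@dataclass
class SimConfig:
    species_newick: str = PRIMATE_NEWICK
    stratum_age_myr: float = DEFAULT_STRATUM_AGE
    r_x: float = DEFAULT_R_X
    r_y: float = DEFAULT_R_Y
    seq_length: int = 5000
    conversions: list = field(default_factory=list)
    deletions: list = field(default_factory=list)
    #: species -> {chromosome -> allele count}; None = one X and one Y each
    sample_plan: dict | None = None
    allele_theta: float = 0.0
    ancestral_rate: float | None = None
    seed: int | None = None

    def to_yaml(self, path) -> None:
        doc = {
            "species_newick": self.species_newick,
            "stratum_age_myr": self.stratum_age_myr,
            "r_x": self.r_x,
            "r_y": self.r_y,
            "seq_length": self.seq_length,
            "allele_theta": self.allele_theta,
            "ancestral_rate": self.ancestral_rate,
            "seed": self.seed,
            "sample_plan": self.sample_plan,
            "conversions": [
                {
                    "lineage": sorted(c.lineage),
                    "time_myr": c.time_myr,
                    "start": c.start,
                    "end": c.end,
                    "direction": c.direction,
                }
                for c in self.conversions
            ],
            "deletions": [
                {
                    "lineage": sorted(d.lineage),
                    "chromosome": d.chromosome,
                    "start": d.start,
                    "end": d.end,
                }
                for d in self.deletions
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["conversions"] = [ConversionSpec(**c) for c in doc.get("conversions") or []]
        doc["deletions"] = [DeletionSpec(**d) for d in doc.get("deletions") or []]
        return cls(**doc)


@dataclass
class SimTruth:
    """Ledger of exactly what the simulator did (the acceptance oracle)."""

    events: list = field(default_factory=list)  # ConversionSpec, realized
    deletions: list = field(default_factory=list)
    subst_counts: dict = field(default_factory=dict)  # (lineage, chrom) -> count
    seed: int | None = None

    def to_tsv(self, path) -> None:
        from .alignio import write_tsv

        rows = [
            ("+".join(sorted(e.lineage)), f"{e.time_myr:g}", e.start, e.end, e.direction)
            for e in self.events
        ]
        write_tsv(path, ("lineage", "time_myr", "start", "end", "direction"), rows)

    def to_bed(self, path, name="region") -> None:
        from .alignio import write_bed

        write_bed(
            path,
            [
                (name, e.start, e.end, f"{'+'.join(sorted(e.lineage))}|{e.direction}|{e.time_myr:g}")
                for e in self.events
            ],
        )


# ---------------------------------------------------------------------------


def jc_expected_p(rate_sum: float, t_years: float) -> float:
    """Expected p-distance between two lineages whose rates sum to
    ``rate_sum`` after ``t_years`` of independent JC evolution."""
    return 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * rate_sum * t_years))


def _evolve(seq: np.ndarray, rate: float, t_myr: float, rng: np.random.Generator):
    """Exact JC step over t_myr; returns (new_seq, n_substitutions)."""
    if t_myr <= 0 or rate <= 0:
        return seq.copy(), 0
    p_change = 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * rate * t_myr * YEARS_PER_MYR))
    out = seq.copy()
    live = np.nonzero(seq != GAP_CODE)[0]
    hit = live[rng.random(live.size) < p_change]
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out, int(hit.size)


def simulate(cfg: SimConfig, seed: int | None = None):
    """Run the forward simulation; returns ``(Alignment, SimTruth)``.

    Same seed, same config => byte-identical output.
    """
    if seed is None:
        seed = cfg.seed if cfg.seed is not None else 0
    rng = np.random.default_rng(seed)
    st = read_species_tree(cfg.species_newick)
    all_species = frozenset(st.species)
    branches = st.branches()
    stem_top = max(cfg.stratum_age_myr, st.root_age)
    branch_windows = dict(branches)
    branch_windows[all_species] = (st.root_age, stem_top)

    by_branch: dict[frozenset, list[ConversionSpec]] = {}
    for conv in cfg.conversions:
        if conv.lineage not in branch_windows:
            raise SimError(f"no branch with descendants {sorted(conv.lineage)}")
        lo, hi = branch_windows[conv.lineage]
        if not (lo <= conv.time_myr <= hi):
            raise SimError(
                f"conversion at {conv.time_myr} myr outside lineage window [{lo}, {hi}]"
            )
        if conv.time_myr > cfg.stratum_age_myr:
            raise SimError("conversion predates the stratum (no X/Y pair yet)")
        if conv.end > cfg.seq_length:
            raise SimError("conversion tract exceeds sequence length")
        by_branch.setdefault(conv.lineage, []).append(conv)
    del_by_branch: dict[frozenset, list[DeletionSpec]] = {}
    for dele in cfg.deletions:
        if dele.lineage not in branch_windows:
            raise SimError(f"no branch with descendants {sorted(dele.lineage)}")
        del_by_branch.setdefault(dele.lineage, []).append(dele)

    anc_rate = cfg.ancestral_rate if cfg.ancestral_rate is not None else 0.5 * (cfg.r_x + cfg.r_y)
    plan = cfg.sample_plan or {s: {"X": 1, "Y": 1} for s in st.species}

    truth = SimTruth(seed=seed)
    counts = truth.subst_counts

    def bump(key, chrom, n):
        counts[(key, chrom)] = counts.get((key, chrom), 0) + n

    def apply_conversion(conv: ConversionSpec, x, y):
        donor, recip = (y, x) if conv.direction == Y_TO_X else (x, y)
        tract = donor[conv.start : conv.end]
        if np.any(tract == GAP_CODE):
            raise SimError(
                f"conversion tract [{conv.start},{conv.end}) overlaps a prior "
                f"deletion on the donor ({'+'.join(sorted(conv.lineage))})"
            )
        recip[conv.start : conv.end] = tract
        truth.events.append(conv)

    def run_branch(key, t_top, t_bot, state):
        """Evolve a lineage from t_top down to t_bot; state is ('single', s)
        or ('pair', x, y). Conversions fire at their times; deletions at the
        bottom of their branch."""
        evs = sorted(by_branch.get(key, []), key=lambda c: -c.time_myr)
        t = t_top
        kind = state[0]
        if kind == "single" and cfg.stratum_age_myr < t and cfg.stratum_age_myr >= t_bot:
            s, n = _evolve(state[1], anc_rate, t - cfg.stratum_age_myr, rng)
            bump(key, "anc", n)
            state = ("pair", s.copy(), s.copy())
            t = cfg.stratum_age_myr
            kind = "pair"
        for conv in evs:
            if kind != "pair":
                raise SimError("conversion scheduled before the stratum fork")
            x, n = _evolve(state[1], cfg.r_x, t - conv.time_myr, rng)
            bump(key, "X", n)
            y, n = _evolve(state[2], cfg.r_y, t - conv.time_myr, rng)
            bump(key, "Y", n)
            apply_conversion(conv, x, y)
            state = ("pair", x, y)
            t = conv.time_myr
        if kind == "pair":
            x, n = _evolve(state[1], cfg.r_x, t - t_bot, rng)
            bump(key, "X", n)
            y, n = _evolve(state[2], cfg.r_y, t - t_bot, rng)
            bump(key, "Y", n)
            state = ("pair", x, y)
        else:
            s, n = _evolve(state[1], anc_rate, t - t_bot, rng)
            bump(key, "anc", n)
            state = ("single", s)
        for dele in del_by_branch.get(key, []):
            if state[0] != "pair":
                raise SimError("deletion scheduled before the stratum fork")
            target = state[1] if dele.chromosome == "X" else state[2]
            target[dele.start : dele.end] = GAP_CODE
            truth.deletions.append(dele)
        return state

    # stem: above the species root
    root_seq = rng.integers(0, 4, size=cfg.seq_length).astype(np.uint8)
    if cfg.stratum_age_myr >= st.root_age:
        state = ("pair", root_seq.copy(), root_seq.copy())
        state = run_branch(all_species, cfg.stratum_age_myr, st.root_age, state)
    else:
        state = run_branch(all_species, st.root_age, st.root_age, ("single", root_seq))

    labels: list[TaxonLabel] = []
    rows: list[np.ndarray] = []

    def descend(node, state):
        for child in node.child_nodes():
            key = frozenset(lf.taxon.label for lf in child.leaf_iter())
            sub = (
                ("single", state[1].copy())
                if state[0] == "single"
                else ("pair", state[1].copy(), state[2].copy())
            )
            sub = run_branch(key, st.node_age(node), st.node_age(child), sub)
            if child.is_leaf():
                emit(child.taxon.label, sub)
            else:
                descend(child, sub)

    def emit(species, state):
        wants = plan.get(species)
        if not wants:
            return
        if state[0] != "pair":
            raise SimError(f"tip {species} reached before the stratum fork")
        _, x, y = state
        for chrom, base, rate in (("X", x, cfg.r_x), ("Y", y, cfg.r_y)):
            k = int(wants.get(chrom, 0))
            for a in range(k):
                seq = base
                if cfg.allele_theta > 0 and rate > 0:
                    t_extra = rng.exponential(cfg.allele_theta / (2.0 * rate)) / YEARS_PER_MYR
                    seq, n = _evolve(base, rate, t_extra, rng)
                    bump(frozenset([species]), chrom, n)
                allele = f"a{a + 1}" if k > 1 else ""
                labels.append(TaxonLabel(species=species, chromosome=chrom, allele_id=allele))
                rows.append(seq.copy())

    descend(st.tree.seed_node, state)
    if len(rows) < 2:
        raise SimError("sample plan yields fewer than 2 sequences")
    seqs = [bytes(_DECODE[r]).decode("ascii") for r in rows]
    return Alignment(labels, seqs), truth


# ---------------------------------------------------------------------------
# Canned scenarios mirroring the study's figures


def make_paper_fixture(name: str, seed: int = 0):
    """Deterministic scenario generators for the study's qualitative setups.

    ``fig1_profile``  — 20 kb human/chimp/rhesus gametologs with one recent
                        human conversion tract (windowed-profile shape).
    ``fig3_ten_events`` — 7.9 kb, five catarrhine species + outgroup, ten
                        conversions laid out over seven sub-regions.
    ``fig4_gibbon``   — four gibbon X alleles + two Y alleles with a planted
                        70-bp Y-identical tract containing 8 diagnostic sites.
    ``fig5_breakpoint`` — 3 kb LINE-like element, reciprocal monophyly on
                        the 5' half, species pairing from column 1500 on.
    ``regionA_null``  — 4 kb stratum backdrop, no conversion anywhere.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; valid: {', '.join(FIXTURE_NAMES)}")
    rng_seed = int(seed)
    if name == "fig1_profile":
        cfg = SimConfig(
            species_newick="(rhesus:30,(human:6,chimp:6):24);",
            seq_length=20000,
            conversions=[ConversionSpec(frozenset(["human"]), 2.5, 8000, 12000, Y_TO_X)],
        )
        return simulate(cfg, rng_seed)
    if name == "regionA_null":
        cfg = SimConfig(
            seq_length=4000,
            sample_plan={
                "nwm": {"X": 1},
                "rhesus": {"X": 1, "Y": 1},
                "human": {"X": 1, "Y": 1},
                "chimp": {"X": 1, "Y": 1},
            },
        )
        return simulate(cfg, rng_seed)
    if name == "fig3_ten_events":
        # seven 4-kb sub-regions scanned with the study's 2-kb windows;
        # event times chosen so every deciding edge carries >=10 expected
        # substitutions per window (donor-lineage length x donor rate)
        hcg = frozenset(["human", "chimp", "gorilla"])
        sched = [
            # sub-region I [0, 4000): gibbon + HCG stem + nested human;
            # the nested event rides on the X->Y stem event, so both human
            # gametologs are X-descended and its direction is X->Y
            ConversionSpec(frozenset(["gibbon"]), 10.0, 0, 4000, Y_TO_X),
            ConversionSpec(hcg, 9.0, 0, 4000, X_TO_Y),
            ConversionSpec(frozenset(["human"]), 1.0, 0, 4000, X_TO_Y),
            # II [4000, 8000): rhesus + HCG stem
            ConversionSpec(frozenset(["rhesus"]), 20.0, 4000, 8000, X_TO_Y),
            ConversionSpec(hcg, 12.0, 4000, 8000, Y_TO_X),
            # III [8000, 12000): gibbon
            ConversionSpec(frozenset(["gibbon"]), 8.0, 8000, 12000, Y_TO_X),
            # IV [12000, 16000): rhesus
            ConversionSpec(frozenset(["rhesus"]), 15.0, 12000, 16000, X_TO_Y),
            # V [16000, 20000): none (reciprocal monophyly)
            # VI [20000, 24000): gibbon + human
            ConversionSpec(frozenset(["gibbon"]), 12.0, 20000, 24000, Y_TO_X),
            ConversionSpec(frozenset(["human"]), 2.0, 20000, 24000, Y_TO_X),
            # VII [24000, 28000): HCG stem
            ConversionSpec(hcg, 9.0, 24000, 28000, X_TO_Y),
        ]
        cfg = SimConfig(
            seq_length=28000,
            conversions=sched,
            sample_plan={
                "nwm": {"X": 1},
                "rhesus": {"X": 1, "Y": 1},
                "gibbon": {"X": 1, "Y": 1},
                "gorilla": {"X": 1, "Y": 1},
                "human": {"X": 1, "Y": 1},
                "chimp": {"X": 1, "Y": 1},
            },
        )
        return simulate(cfg, rng_seed)
    if name == "fig5_breakpoint":
        cfg = SimConfig(
            species_newick="(rhesus:30,(human:6,chimp:6):24);",
            seq_length=3000,
            conversions=[
                ConversionSpec(frozenset(["human"]), 3.0, 1500, 3000, Y_TO_X),
                ConversionSpec(frozenset(["chimp"]), 4.0, 1500, 3000, X_TO_Y),
                ConversionSpec(frozenset(["rhesus"]), 15.0, 1500, 3000, Y_TO_X),
            ],
        )
        return simulate(cfg, rng_seed)
    # fig4_gibbon: simulate allele diversity, then plant the tract exactly
    cfg = SimConfig(
        species_newick="(gibbon:18,(gorilla:8,(human:6,chimp:6):2):10);",
        seq_length=2000,
        sample_plan={"gibbon": {"X": 4, "Y": 2}},
        allele_theta=0.002,
    )
    aln, truth = simulate(cfg, rng_seed)
    return _plant_gibbon_tract(aln, truth)


def _plant_gibbon_tract(aln: Alignment, truth: SimTruth, start: int = 960, length: int = 70):
    """Overwrite a 70-bp window so the first X allele is identical to the
    first Y allele across it, with exactly 8 diagnostic sites, and fixed
    X/Y differences flanking the window so the run is exactly 70 bp."""
    codes = aln.codes.copy()
    x_rows = [i for i, t in enumerate(aln.taxa) if t.chromosome == "X"]
    y_rows = [i for i, t in enumerate(aln.taxa) if t.chromosome == "Y"]
    focal = x_rows[0]
    end = start + length
    diag_offsets = [4, 13, 22, 31, 40, 49, 58, 67]
    for c in range(start, end):
        base = codes[x_rows[1], c] % 4
        if (c - start) in diag_offsets:
            ystate = (base + 1) % 4
            for r in x_rows:
                codes[r, c] = base
            for r in y_rows:
                codes[r, c] = ystate
            codes[focal, c] = ystate
        else:
            for r in x_rows + y_rows:
                codes[r, c] = base
    for c in (start - 1, end):  # hard X/Y difference bounding the run
        base = codes[x_rows[1], c] % 4
        for r in x_rows:
            codes[r, c] = base
        for r in y_rows:
            codes[r, c] = (base + 1) % 4
    # codes uses MISSING for ambiguity; none present here (no deletions)
    seqs = [bytes(_DECODE[np.minimum(row, GAP_CODE)]).decode("ascii") for row in codes]
    planted = ConversionSpec(
        frozenset(["gibbon"]), 0.0, start, end, Y_TO_X
    )
    truth.events.append(planted)
    return Alignment(aln.taxa, seqs), truth
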