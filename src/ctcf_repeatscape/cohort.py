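"""Synthetic multi-species cohort generator.

Generates six mammal-like genomes with the statistical structure the
comparative CTCF analysis assumes, plus truth tables for every planted
quantity, so the whole pipeline is testable without any downloads:

* an ancestral genome evolved down a fixed species tree by independent
  per-site substitution (Jukes-Cantor per branch; no indels inside blocks,
  so cross-species coordinates stay exact);
* planted two-part motif instances (M1, optionally M2 at a 20 or 21 bp
  center spacing) drawn from a word pool whose usage frequency correlates
  with the probability of being conserved, under purifying selection at
  conserved motif bases;
* lineage-specific repeat expansions whose consensus carries a lineage
  motif-word, inserted as new unaligned blocks absent from other species;
* binding events with ChIP-like scores, H2AK5ac domains abutting a planted
  subset of events, and tandem gene pairs with a planted insulation shift.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dna
from .motif_scan import PWM
from .ortho_sharing import ALL_SPECIES, CODE_SPECIES, BlockMap

logger = logging.getLogger(__name__)


class CohortSizingError(ValueError):
    """The genome is too small to host the requested sites/repeats/genes."""


@dataclass(frozen=True)
class SpeciesTree:
    """Fixed-order species tree with branch lengths in substitutions/site."""

    species: tuple[str, ...]
    parents: dict[str, str | None]
    branch_lengths: dict[str, float]

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parents.items() if p is None]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        if any(b < 0 for b in self.branch_lengths.values()):
            raise ValueError("branch lengths must be >= 0")

    @property
    def root(self) -> str:
        return next(n for n, p in self.parents.items() if p is None)

    def topological_order(self) -> list[str]:
        order, seen = [], set()

        def visit(node: str) -> None:
            if node in seen:
                return
            parent = self.parents[node]
            if parent is not None:
                visit(parent)
            seen.add(node)
            order.append(node)

        for node in self.parents:
            visit(node)
        return order

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two nodes."""

        def ancestors(n: str) -> list[str]:
            out = [n]
            while self.parents[out[-1]] is not None:
                out.append(self.parents[out[-1]])
            return out

        anc_a, anc_b = ancestors(a), ancestors(b)
        common = next(n for n in anc_a if n in set(anc_b))
        dist = 0.0
        for path, stop in ((anc_a, common), (anc_b, common)):
            for n in path:
                if n == stop:
                    break
                dist += self.branch_lengths[n]
        return dist


def default_tree() -> SpeciesTree:
    """Six-species tree: ((human, macaque), (mouse, rat), dog) + opossum outgroup."""
    parents = {
        "root": None,
        "eutherian": "root",
        "primate": "eutherian",
        "rodent": "eutherian",
        "human": "primate",
        "macaque": "primate",
        "mouse": "rodent",
        "rat": "rodent",
        "dog": "eutherian",
        "opossum": "root",
    }
    lengths = {
        "eutherian": 0.12,
        "primate": 0.08,
        "rodent": 0.12,
        "human": 0.04,
        "macaque": 0.04,
        "mouse": 0.06,
        "rat": 0.06,
        "dog": 0.16,
        "opossum": 0.35,
    }
    return SpeciesTree(species=ALL_SPECIES, parents=parents, branch_lengths=lengths)


@dataclass(frozen=True)
class RepeatExpansionSpec:
    """One lineage-specific repeat expansion carrying a motif word.

    ``word_substitutions`` defines the lineage word as substitutions applied
    to the consensus motif-word: tuples of (word position, cyclic base offset
    1-3).  ``with_m2`` adds an M2 instance at ``m2_spacing`` bp center-to-
    center.
    """

    name: str
    family: str
    repeat_class: str
    species: tuple[str, ...]
    n_copies: int
    divergence_mean: float
    bound_fraction: float = 0.6
    consensus_length: int = 190
    motif_offset: int = 60
    with_m2: bool = False
    m2_spacing: int = 20
    word_substitutions: tuple[tuple[int, str], ...] = ()
    carries_motif: bool = True

    def __post_init__(self) -> None:
        if self.n_copies < 0:
            raise ValueError("n_copies must be >= 0")
        if not 0.0 <= self.divergence_mean <= 1.0:
            raise ValueError("divergence_mean must be in [0, 1]")


def default_expansions() -> tuple[RepeatExpansionSpec, ...]:
    """Rodent-shared and mouse-specific B2-like SINEs (M1+M2 at 20 bp), a dog
    SINEC-like and an opossum MIR-like M1-only family, and a motif-free decoy."""
    return (
        RepeatExpansionSpec(
            name="B2_Mm1", family="B2", repeat_class="SINE",
            species=("mouse", "rat"), n_copies=300, divergence_mean=0.05,
            with_m2=True, m2_spacing=20, word_substitutions=((0, 1),),
        ),
        RepeatExpansionSpec(
            name="B2_Mm2", family="B2", repeat_class="SINE",
            species=("mouse",), n_copies=300, divergence_mean=0.03,
            with_m2=True, m2_spacing=20, word_substitutions=((0, 1),),
        ),
        RepeatExpansionSpec(
            name="SINEC_Cf", family="Lys", repeat_class="SINE",
            species=("dog",), n_copies=200, divergence_mean=0.05,
            word_substitutions=((4, 1),),
        ),
        RepeatExpansionSpec(
            name="MAR1_Mdo", family="MIR", repeat_class="SINE",
            species=("opossum",), n_copies=200, divergence_mean=0.06,
            word_substitutions=((12, 1),),
        ),
        RepeatExpansionSpec(
            name="DecoyRep", family="Decoy", repeat_class="LINE",
            species=("mouse",), n_copies=300, divergence_mean=0.10,
            bound_fraction=0.0, carries_motif=False,
        ),
    )


def scaled_expansions(
    expansions: tuple[RepeatExpansionSpec, ...], scale: float
) -> tuple[RepeatExpansionSpec, ...]:
    """Copy-number-scaled expansion specs (for sub-study-size genomes)."""
    import dataclasses

    return tuple(
        dataclasses.replace(spec, n_copies=int(round(spec.n_copies * scale)))
        for spec in expansions
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic cohort (deterministic given seed)."""

    seed: int
    genome_length: int = 5_000_000
    tree: SpeciesTree = field(default_factory=default_tree)
    # planted motif sites
    n_sites: int = 2_000
    conserved_fraction: float = 0.3
    m2_fraction: float = 0.5
    m2_spacings: tuple[int, ...] = (20, 21)
    m2_spacing_probs: tuple[float, ...] = (0.5, 0.5)
    purifying_factor: float = 0.1
    n_words: int = 50
    zipf_exponent: float = 1.3
    site_min_separation: int = 1_500
    peak_halfwidth: int = 200
    # repeat expansions
    expansions: tuple[RepeatExpansionSpec, ...] = field(default_factory=default_expansions)
    repeat_min_separation: int = 800
    repeat_site_clearance: int = 300
    # chromatin domains (one species)
    barrier_species: str = "mouse"
    barrier_fraction: float = 0.05
    n_background_domains: int = 20
    domain_length_range: tuple[int, int] = (4_000, 30_000)
    coverage_bin_size: int = 100
    coverage_background_rate: float = 1.0
    coverage_domain_rate: float = 8.0
    # tandem genes and expression (one species)
    expression_species: str = "mouse"
    n_insulated_pairs: int = 200
    n_control_pairs: int = 200
    gene_length: int = 1_000
    gene_gap_range: tuple[int, int] = (500, 1_800)
    n_replicates: int = 2
    expression_baseline_sd: float = 1.5
    pair_delta_sd: float = 0.5
    replicate_noise_sd: float = 0.1
    insulation_shift: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for frac in (self.conserved_fraction, self.m2_fraction, self.purifying_factor):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions/rates must be in [0, 1]")
        if self.n_sites < 0 or self.genome_length <= 0:
            raise ValueError("counts must be >= 0 and genome length > 0")


# fixed generating-motif geometry: M1 is 20 bp with 14 informative positions
M1_LENGTH = 20
M2_LENGTH = 9
INFORMATIVE_POSITIONS = np.array([0, 1, 2, 3, 4, 6, 7, 8, 10, 11, 13, 14, 16, 17])
STRONG_WORD_POSITIONS = (0, 2, 4, 6, 8, 10, 12, 13)  # indices into the 14-mer
FOOTPRINT_M2_MAX = 36  # M1 start .. M2 end at spacing 21


def _generating_pwms(rng: np.random.Generator) -> tuple[PWM, PWM]:
    """Strong-but-degenerate M1 (14 informative + 6 near-uniform columns), sharp M2."""
    m1 = np.zeros((M1_LENGTH, 4))
    weak = np.array([0.30, 0.25, 0.25, 0.20])
    strong_info = {INFORMATIVE_POSITIONS[i] for i in STRONG_WORD_POSITIONS}
    for pos in range(M1_LENGTH):
        if pos in set(INFORMATIVE_POSITIONS):
            dominant = rng.integers(0, 4)
            p_dom = 0.85 if pos in strong_info else 0.70
            m1[pos] = (1.0 - p_dom) / 3.0
            m1[pos, dominant] = p_dom
        else:
            m1[pos] = rng.permutation(weak)
    m2 = np.full((M2_LENGTH, 4), 0.05)
    for pos in range(M2_LENGTH):
        m2[pos, rng.integers(0, 4)] = 0.85
    return PWM(m1), PWM(m2)


#: word positions held by the lower-IC informative columns (pool words vary here)
WEAK_WORD_POSITIONS = tuple(
    i for i in range(len(INFORMATIVE_POSITIONS)) if i not in STRONG_WORD_POSITIONS
)


def _sample_word_pool(m1: PWM, n_words: int, rng: np.random.Generator) -> list[str]:
    """Distinct 14-mers within two substitutions of the consensus.

    Variants touch only the degenerate (lower-IC) informative columns so every
    pool word stays comfortably above the study scan cutoff; pool[0] is the
    consensus word.
    """
    cols = m1.probs[INFORMATIVE_POSITIONS]
    consensus = np.argmax(cols, axis=1).astype(np.uint8)
    pool = [dna.decode(consensus)]
    seen = set(pool)
    tries = 0
    weak = np.array(WEAK_WORD_POSITIONS)
    while len(pool) < n_words:
        tries += 1
        if tries > n_words * 500:
            raise RuntimeError("could not sample enough distinct motif-words")
        n_sub = 1 if rng.random() < 0.35 else 2
        positions = rng.choice(weak, size=n_sub, replace=False)
        word = consensus.copy()
        word[positions] = (word[positions] + rng.integers(1, 4, size=n_sub)) % 4
        w = dna.decode(word)
        if w not in seen:
            pool.append(w)
            seen.add(w)
    return pool


def _lineage_word(consensus_word: str, substitutions, pool: list[str]) -> str:
    """Lineage word = consensus with base offsets applied at the given word
    positions; offsets are cyclic (1-3) so the result always differs from the
    consensus.  If it collides with a pool word, additional deterministic weak-
    position offsets are tried until it is distinct."""
    base = dna.encode(consensus_word)
    word = base.copy()
    for pos, offset in substitutions:
        word[pos] = (word[pos] + offset) % 4
    cand = dna.decode(word)
    taken = set(pool)
    extra = 0
    while cand in taken:
        w = word.copy()
        pos = WEAK_WORD_POSITIONS[extra % len(WEAK_WORD_POSITIONS)]
        w[pos] = (w[pos] + 1 + extra // len(WEAK_WORD_POSITIONS)) % 4
        cand = dna.decode(w)
        extra += 1
    return cand


def _jc_substitute(
    seq: np.ndarray,
    branch_length: float,
    rng: np.random.Generator,
    purified: np.ndarray | None = None,
    factor: float = 1.0,
) -> np.ndarray:
    """One branch of Jukes-Cantor evolution; purified positions use rate*factor.

    The per-site substitution probability for branch length b is the exact JC
    transition probability 3/4*(1-exp(-4b/3)), so corrected leaf-leaf
    distances are additive along the tree.
    """

    def p_sub(b: float) -> float:
        return 0.75 * (1.0 - np.exp(-4.0 * b / 3.0))

    out = seq.copy()
    p = np.full(seq.size, p_sub(branch_length))
    if purified is not None and purified.size:
        p[purified] = p_sub(branch_length * factor)
    hit = np.where(rng.random(seq.size) < p)[0]
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out.astype(np.uint8)


def _mutate_copy(
    consensus: np.ndarray, divergence_mean: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Per-base substitution at probability divergence_mean; true count returned."""
    hit = np.where(rng.random(consensus.size) < divergence_mean)[0]
    copy = consensus.copy()
    if hit.size:
        copy[hit] = (copy[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return copy, int(hit.size)


def _pack_positions(
    n: int, length: int, separation: int, margin: int, rng: np.random.Generator
) -> np.ndarray:
    """n sorted positions in [margin, length-margin) at pairwise >= separation."""
    slack = length - 2 * margin - n * separation
    if n > 0 and slack <= 0:
        raise CohortSizingError(
            f"genome of {length} bp cannot host {n} sites at separation {separation}"
        )
    if n == 0:
        return np.array([], dtype=np.int64)
    u = np.sort(rng.random(n)) * slack
    return (margin + u + np.arange(n) * separation).astype(np.int64)


@dataclass
class TruthTables:
    """Planted coordinates and labels for every downstream recovery test."""

    sites: pd.DataFrame  # one row per planted ancestral site
    repeats: pd.DataFrame  # one row per (copy, species)
    barrier_event_ids: list[str]
    insulated_pairs: pd.DataFrame  # upstream/downstream gene ids
    lineage_words: dict[str, str]  # expansion name -> planted word


@dataclass
class Cohort:
    """Everything the pipeline consumes, plus generating truth."""

    config: SimulationConfig
    genomes: dict[str, np.ndarray]
    block_map: BlockMap
    events: dict[str, pd.DataFrame]
    repeats: dict[str, pd.DataFrame]
    truth: TruthTables
    m1_pwm: PWM
    m2_pwm: PWM
    word_pool: list[str]
    word_weights: np.ndarray
    domains: pd.DataFrame
    coverage: np.ndarray | None
    genes: pd.DataFrame
    expression: pd.DataFrame

    @property
    def species(self) -> tuple[str, ...]:
        return self.config.tree.species

    def bound_regions(self, species: str) -> pd.DataFrame:
        return self.events[species][["chrom", "start", "end"]]

    def genome_fasta(self, species: str) -> str:
        return dna.decode(self.genomes[species])

    def to_dir(self, path) -> None:
        """Write genomes, annotations and truth tables as FASTA/TSV text."""
        from pathlib import Path

        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        for sp in self.species:
            rec = SeqRecord(Seq(self.genome_fasta(sp)), id="chr1", description=f"{sp} synthetic")
            seqio_write([rec], out / f"{sp}.fa", "fasta")
            self.events[sp].to_csv(out / f"{sp}.events.tsv", sep="\t", index=False)
            self.repeats[sp].to_csv(out / f"{sp}.repeats.tsv", sep="\t", index=False)
        self.block_map.to_tsv(out / "block_map.tsv")
        self.truth.sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
        self.truth.repeats.to_csv(out / "truth_repeats.tsv", sep="\t", index=False)
        self.domains.to_csv(out / "domains.tsv", sep="\t", index=False)
        self.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
        self.expression.to_csv(out / "expression.tsv", sep="\t")


def _site_sequence(
    m1: PWM,
    word: str,
    has_m2: bool,
    spacing: int,
    m2_consensus: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Encoded footprint sequence and its motif-base offsets (for purifying)."""
    length = (M1_LENGTH // 2 + spacing + M2_LENGTH // 2 + 1) if has_m2 else M1_LENGTH
    seq = rng.integers(0, 4, size=length).astype(np.uint8)
    m1_seq = np.empty(M1_LENGTH, dtype=np.uint8)
    for pos in range(M1_LENGTH):
        m1_seq[pos] = rng.choice(4, p=m1.probs[pos])
    m1_seq[INFORMATIVE_POSITIONS] = dna.encode(word)
    seq[:M1_LENGTH] = m1_seq
    motif_offsets = list(range(M1_LENGTH))
    if has_m2:
        m2_start = M1_LENGTH // 2 + spacing - M2_LENGTH // 2
        seq[m2_start : m2_start + M2_LENGTH] = m2_consensus
        motif_offsets += list(range(m2_start, m2_start + M2_LENGTH))
    return seq, np.array(motif_offsets, dtype=np.int64)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the cohort; byte-identical outputs for identical configs."""
    streams = np.random.SeedSequence(config.seed).spawn(8)
    rng_motif, rng_anc, rng_sites, rng_evo, rng_rep, rng_chip, rng_dom, rng_gene = (
        np.random.default_rng(s) for s in streams
    )
    tree = config.tree
    L = config.genome_length

    m1_pwm, m2_pwm = _generating_pwms(rng_motif)
    m2_consensus = dna.encode(m2_pwm.consensus)
    pool = _sample_word_pool(m1_pwm, config.n_words, rng_motif)
    weights = (np.arange(1, config.n_words + 1, dtype=float)) ** (-config.zipf_exponent)
    weights /= weights.sum()
    # conservation propensity rises with word usage weight
    rel = (weights / weights.mean()) ** 0.4
    p_cons = np.clip(config.conserved_fraction * rel / np.dot(weights, rel), 0.02, 0.95)

    ancestor = dna.random_seq(L, rng_anc)

    # ---- planted sites in the ancestor -------------------------------------
    positions = _pack_positions(
        config.n_sites, L, config.site_min_separation, 1_000, rng_sites
    )
    site_rows = []
    site_motif_positions: list[np.ndarray] = []
    site_bound_sets: list[set[str]] = []
    for i, pos in enumerate(positions):
        widx = int(rng_sites.choice(config.n_words, p=weights))
        conserved = bool(rng_sites.random() < p_cons[widx])
        has_m2 = bool(rng_sites.random() < config.m2_fraction)
        spacing = int(rng_sites.choice(config.m2_spacings, p=config.m2_spacing_probs))
        strand = "+" if rng_sites.random() < 0.5 else "-"
        seq, offsets = _site_sequence(
            m1_pwm, pool[widx], has_m2, spacing, m2_consensus, rng_sites
        )
        if strand == "-":
            seq_w = dna.revcomp(seq)
            offsets = seq.size - 1 - offsets[::-1]
        else:
            seq_w = seq
        ancestor[pos : pos + seq.size] = seq_w
        site_motif_positions.append(pos + offsets)
        if conserved:
            bound = set(tree.species)
        else:
            bound = {tree.species[rng_sites.integers(0, len(tree.species))]}
        site_bound_sets.append(bound)
        code = "".join("1" if sp in bound else "0" for sp in CODE_SPECIES)
        site_rows.append(
            {
                "site_id": f"site_{i:05d}",
                "anc_pos": int(pos),
                "footprint": int(seq.size),
                "word_index": widx,
                "word": pool[widx],
                "strand": strand,
                "has_m2": has_m2,
                "spacing": spacing if has_m2 else -1,
                "conserved": conserved,
                "bound_species": ",".join(sp for sp in tree.species if sp in bound),
                "code": code,
            }
        )
    sites = pd.DataFrame(
        site_rows,
        columns=[
            "site_id", "anc_pos", "footprint", "word_index", "word", "strand",
            "has_m2", "spacing", "conserved", "bound_species", "code",
        ],
    )
    # ---- evolve core sequence down the tree --------------------------------
    # purifying selection acts on a site's motif bases along every branch
    # leading to a species where the site is bound (conserved sites are
    # purified everywhere; species-specific sites only on their own path)
    children: dict[str, list[str]] = {}
    for node, parent in tree.parents.items():
        if parent is not None:
            children.setdefault(parent, []).append(node)

    def leaves_below(node: str) -> set[str]:
        if node not in children:
            return {node}
        out: set[str] = set()
        for ch in children[node]:
            out |= leaves_below(ch)
        return out

    empty = np.array([], dtype=np.int64)
    node_purified: dict[str, np.ndarray] = {}
    for node in tree.topological_order():
        if node == tree.root:
            continue
        below = leaves_below(node)
        masks = [
            site_motif_positions[i]
            for i in range(len(site_bound_sets))
            if site_bound_sets[i] & below
        ]
        node_purified[node] = np.concatenate(masks) if masks else empty

    node_seqs: dict[str, np.ndarray] = {tree.root: ancestor}
    for node in tree.topological_order():
        if node == tree.root:
            continue
        parent = tree.parents[node]
        node_seqs[node] = _jc_substitute(
            node_seqs[parent],
            tree.branch_lengths[node],
            rng_evo,
            purified=node_purified[node],
            factor=config.purifying_factor,
        )
    core = {sp: node_seqs[sp] for sp in tree.species}

    # ---- repeat expansions as new unaligned blocks -------------------------
    consensus_word = pool[0]
    lineage_words: dict[str, str] = {}
    site_excl_lo = positions - config.repeat_site_clearance
    site_excl_hi = positions + sites["footprint"].to_numpy(np.int64) + config.repeat_site_clearance if len(sites) else positions

    def near_site(p: int) -> bool:
        if positions.size == 0:
            return False
        j = np.searchsorted(site_excl_lo, p, side="right") - 1
        if j >= 0 and p < site_excl_hi[j]:
            return True
        return False

    insertions: list[dict] = []  # anc_pos, spec, copy ordinal, consensus array
    taken = []
    for spec in config.expansions:
        cons = dna.random_seq(spec.consensus_length, rng_rep)
        if spec.carries_motif:
            word = _lineage_word(consensus_word, spec.word_substitutions, pool)
            lineage_words[spec.name] = word
            m1_seq = np.argmax(m1_pwm.probs, axis=1).astype(np.uint8)
            m1_seq[INFORMATIVE_POSITIONS] = dna.encode(word)
            off = spec.motif_offset
            cons[off : off + M1_LENGTH] = m1_seq
            if spec.with_m2:
                m2_start = off + M1_LENGTH // 2 + spec.m2_spacing - M2_LENGTH // 2
                cons[m2_start : m2_start + M2_LENGTH] = m2_consensus
        placed = 0
        tries = 0
        max_tries = max(spec.n_copies * 300, 1)
        while placed < spec.n_copies:
            tries += 1
            if tries > max_tries:
                raise CohortSizingError(
                    f"could not place {spec.n_copies} copies of {spec.name}: "
                    f"insufficient free sequence"
                )
            p = int(rng_rep.integers(1_000, L - 1_000))
            if near_site(p):
                continue
            j = bisect.bisect_left(taken, p)
            if (j > 0 and p - taken[j - 1] < config.repeat_min_separation) or (
                j < len(taken) and taken[j] - p < config.repeat_min_separation
            ):
                continue
            taken.insert(j, p)
            insertions.append(
                {"anc_pos": p, "spec": spec, "ordinal": placed, "consensus": cons}
            )
            placed += 1

    insertions.sort(key=lambda r: r["anc_pos"])
    ins_pos = np.array([r["anc_pos"] for r in insertions], dtype=np.int64)
    ins_len = np.array([r["spec"].consensus_length for r in insertions], dtype=np.int64)

    # per-species copy sequences and true substitution counts
    copy_seqs: dict[tuple[int, str], tuple[np.ndarray, int, bool]] = {}
    for i, rec in enumerate(insertions):
        spec = rec["spec"]
        for sp in spec.species:
            seq, subs = _mutate_copy(rec["consensus"], spec.divergence_mean, rng_rep)
            bound = bool(rng_rep.random() < spec.bound_fraction)
            copy_seqs[(i, sp)] = (seq, subs, bound)

    # ---- assemble genomes and the block map --------------------------------
    ins_mask = {
        sp: np.array([sp in r["spec"].species for r in insertions], dtype=bool)
        for sp in tree.species
    }
    ins_cum_through = {
        sp: np.cumsum(np.where(ins_mask[sp], ins_len, 0)) for sp in tree.species
    }

    def anc_to_species(sp: str, q: np.ndarray) -> np.ndarray:
        """Species coordinate of ancestral position q (core sequence)."""
        k = np.searchsorted(ins_pos, q, side="right")
        through = np.concatenate([[0], ins_cum_through[sp]])
        return q + through[k]

    block_rows = []
    genomes: dict[str, np.ndarray] = {}
    core_bounds = np.concatenate([[0], ins_pos, [L]])
    for sp in tree.species:
        parts = []
        cur = 0
        for j in range(len(core_bounds) - 1):
            a, b = int(core_bounds[j]), int(core_bounds[j + 1])
            if b > a:
                parts.append(core[sp][a:b])
                block_rows.append(
                    {
                        "block_id": f"core_{j:05d}",
                        "species": sp,
                        "chrom": "chr1",
                        "start": cur,
                        "end": cur + (b - a),
                        "strand": "+",
                    }
                )
                cur += b - a
            if j < len(ins_pos) and ins_mask[sp][j]:
                seq, _, _ = copy_seqs[(j, sp)]
                parts.append(seq)
                block_rows.append(
                    {
                        "block_id": f"ins_{insertions[j]['spec'].name}_{insertions[j]['ordinal']:05d}",
                        "species": sp,
                        "chrom": "chr1",
                        "start": cur,
                        "end": cur + seq.size,
                        "strand": "+",
                    }
                )
                cur += seq.size
        genomes[sp] = np.concatenate(parts) if parts else np.array([], dtype=np.uint8)
    block_map = BlockMap(pd.DataFrame(block_rows))

    # ---- per-species site coordinates and binding events -------------------
    for sp in tree.species:
        sites[f"pos_{sp}"] = anc_to_species(sp, sites["anc_pos"].to_numpy(np.int64)) if len(sites) else []

    hw = config.peak_halfwidth
    events: dict[str, pd.DataFrame] = {}
    repeat_rows: list[dict] = []
    for sp in tree.species:
        rows = []
        glen = genomes[sp].size
        for row in sites.itertuples(index=False):
            if sp not in row.bound_species.split(","):
                continue
            summit = int(getattr(row, f"pos_{sp}")) + row.footprint // 2
            w = weights[row.word_index]
            score = 5.0 + 8.0 * (w / weights[0]) ** 0.3 + rng_chip.normal(0.0, 1.0)
            rows.append(
                {
                    "chrom": "chr1",
                    "start": max(summit - hw, 0),
                    "end": min(summit + hw, glen),
                    "summit": summit,
                    "score": round(float(score), 3),
                    "source": "site",
                    "origin_id": row.site_id,
                }
            )
        for i, rec in enumerate(insertions):
            spec = rec["spec"]
            if sp not in spec.species:
                continue
            seq, subs, bound = copy_seqs[(i, sp)]
            start = int(anc_to_species(sp, np.array([rec["anc_pos"]]))[0] - ins_len[i])
            copy_id = f"{spec.name}_{rec['ordinal']:05d}"
            repeat_rows.append(
                {
                    "species": sp,
                    "chrom": "chr1",
                    "start": start,
                    "end": start + seq.size,
                    "strand": "+",
                    "name": spec.name,
                    "family": spec.family,
                    "class": spec.repeat_class,
                    "substitutions": subs,
                    "consensus_length": spec.consensus_length,
                    "bound": bound,
                    "copy_id": copy_id,
                }
            )
            if bound and spec.carries_motif:
                summit = start + spec.motif_offset + M1_LENGTH // 2
                rows.append(
                    {
                        "chrom": "chr1",
                        "start": max(summit - hw, 0),
                        "end": min(summit + hw, glen),
                        "summit": summit,
                        "score": round(float(rng_chip.normal(8.0, 1.0)), 3),
                        "source": spec.name,
                        "origin_id": copy_id,
                    }
                )
        df = pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "summit", "score", "source", "origin_id"],
        ).sort_values("start", kind="stable").reset_index(drop=True)
        df.insert(0, "event_id", [f"{sp}_{k:05d}" for k in range(len(df))])
        events[sp] = df
    repeats_df = pd.DataFrame(
        repeat_rows,
        columns=[
            "species", "chrom", "start", "end", "strand", "name", "family", "class",
            "substitutions", "consensus_length", "bound", "copy_id",
        ],
    )
    repeats = {
        sp: repeats_df[repeats_df["species"] == sp].reset_index(drop=True)
        for sp in tree.species
    }

    # ---- H2AK5ac domains + coverage in the barrier species -----------------
    bsp = config.barrier_species
    conserved_ids = set(sites.loc[sites["conserved"], "site_id"]) if len(sites) else set()
    bsp_labels = (
        event_category(events[bsp], config.expansions, bsp, conserved_ids)
        if bsp in events
        else None
    )
    domains, coverage, barrier_ids = _plant_domains(
        config, events.get(bsp), genomes.get(bsp), bsp_labels, rng_dom
    )

    # ---- tandem genes + expression in the expression species ---------------
    esp = config.expression_species
    genes, expression, insulated = _plant_genes(config, events.get(esp), genomes.get(esp), rng_gene)

    truth = TruthTables(
        sites=sites,
        repeats=repeats_df,
        barrier_event_ids=barrier_ids,
        insulated_pairs=insulated,
        lineage_words=lineage_words,
    )
    return Cohort(
        config=config,
        genomes=genomes,
        block_map=block_map,
        events=events,
        repeats=repeats,
        truth=truth,
        m1_pwm=m1_pwm,
        m2_pwm=m2_pwm,
        word_pool=pool,
        word_weights=weights,
        domains=domains,
        coverage=coverage,
        genes=genes,
        expression=expression,
    )


def event_category(
    events: pd.DataFrame,
    expansions: tuple[RepeatExpansionSpec, ...],
    species: str,
    conserved_site_ids: set[str] | None = None,
) -> pd.Series:
    """Truth-based event category: five_way (conserved planted site),
    specific_rab / shared_rab (species-specific vs lineage-shared repeat
    expansions), or all_other."""
    by_name = {s.name: s for s in expansions}
    conserved_site_ids = conserved_site_ids or set()
    cats = []
    for row in events.itertuples(index=False):
        spec = by_name.get(row.source)
        if spec is not None:
            cats.append("specific_rab" if spec.species == (species,) else "shared_rab")
        elif row.origin_id in conserved_site_ids:
            cats.append("five_way")
        else:
            cats.append("all_other")
    return pd.Series(cats, index=events.index)


def _plant_domains(config, events, genome, labels, rng):
    cols = ["domain_id", "start", "end", "length"]
    if events is None or genome is None or len(events) == 0 or config.barrier_fraction <= 0:
        return pd.DataFrame(columns=cols), None, []
    glen = int(genome.size)
    placed: list[tuple[int, int]] = []
    rows = []
    barrier_ids: list[str] = []
    lmin, lmax = config.domain_length_range

    def free(a: int, b: int) -> bool:
        return 0 <= a < b <= glen and not any(a < e + 200 and b + 200 > s for s, e in placed)

    k = 0
    for label in ("five_way", "specific_rab", "shared_rab", "all_other"):
        pool_idx = events.index[labels == label]
        n_plant = int(round(config.barrier_fraction * len(pool_idx)))
        if n_plant == 0:
            continue
        chosen = rng.choice(pool_idx.to_numpy(), size=n_plant, replace=False)
        for idx in chosen:
            summit = int(events.loc[idx, "summit"])
            ok = False
            for _ in range(50):
                l = int(rng.integers(lmin, lmax + 1))
                dmax = int(min(l / 10.0, 1000.0))
                d = int(rng.integers(0, dmax + 1))
                b = summit + d if rng.random() < 0.5 else summit - d
                if rng.random() < 0.5:
                    a, z = b, b + l
                else:
                    a, z = b - l, b
                if free(a, z):
                    placed.append((a, z))
                    rows.append({"domain_id": f"dom_{k:04d}", "start": a, "end": z, "length": l})
                    barrier_ids.append(events.loc[idx, "event_id"])
                    k += 1
                    ok = True
                    break
            if not ok:
                logger.info("could not place a domain for event %s", events.loc[idx, "event_id"])
    for _ in range(config.n_background_domains):
        for _ in range(50):
            l = int(rng.integers(lmin, lmax + 1))
            a = int(rng.integers(0, max(glen - l, 1)))
            if free(a, a + l):
                placed.append((a, a + l))
                rows.append({"domain_id": f"dom_{k:04d}", "start": a, "end": a + l, "length": l})
                k += 1
                break
    domains = pd.DataFrame(rows, columns=cols).sort_values("start").reset_index(drop=True)
    nbins = int(np.ceil(glen / config.coverage_bin_size))
    lam = np.full(nbins, config.coverage_background_rate)
    for row in domains.itertuples(index=False):
        lam[row.start // config.coverage_bin_size : int(np.ceil(row.end / config.coverage_bin_size))] = (
            config.coverage_domain_rate
        )
    coverage = rng.poisson(lam)
    return domains, coverage, barrier_ids


def _plant_genes(config, events, genome, rng):
    gene_cols = ["gene", "chrom", "start", "end", "strand"]
    pair_cols = ["pair_id", "upstream_gene", "downstream_gene", "insulated", "event_summit"]
    if events is None or genome is None or (config.n_insulated_pairs + config.n_control_pairs) == 0:
        return (
            pd.DataFrame(columns=gene_cols),
            pd.DataFrame(),
            pd.DataFrame(columns=pair_cols),
        )
    glen = int(genome.size)
    summits = np.sort(events["summit"].to_numpy(np.int64))
    glength = config.gene_length
    gmin, gmax = config.gene_gap_range
    clearance = gmax + 700

    # anchors must be far enough apart that neighboring pairs' genes cannot
    # interleave (which would break genomic adjacency within a pair): the
    # widest possible span between two pairs' inner genes is g2+g1+gene length
    min_anchor_gap = 2 * gmax + glength + 200

    accepted: list[int] = []

    def accept(x: int) -> bool:
        j = bisect.bisect_left(accepted, x)
        if (j > 0 and x - accepted[j - 1] < min_anchor_gap) or (
            j < len(accepted) and accepted[j] - x < min_anchor_gap
        ):
            return False
        accepted.insert(j, x)
        return True

    # insulated anchors: summits isolated from other summits
    gaps_prev = np.diff(np.concatenate([[-(10**9)], summits]))
    gaps_next = np.diff(np.concatenate([summits, [10**9]]))
    isolated = (gaps_prev > clearance) & (gaps_next > clearance)
    edge_ok = (summits > glength + gmax + 100) & (summits < glen - glength - gmax - 100)
    candidates = rng.permutation(summits[isolated & edge_ok])
    anchors: list[int] = []
    for x in candidates:
        if len(anchors) >= config.n_insulated_pairs:
            break
        if accept(int(x)):
            anchors.append(int(x))
    if len(anchors) < config.n_insulated_pairs:
        raise CohortSizingError(
            f"only {len(anchors)} isolated events for {config.n_insulated_pairs} insulated pairs"
        )
    accepted = sorted(anchors)

    # control anchors: points whose prospective gap interval (+- max gene gap)
    # contains no event summit; long event-free stretches host several
    bounds = np.concatenate([[0], summits, [glen]])
    margin = gmax + 100
    free_rows: list[int] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        lo = int(a) + margin + glength
        hi = int(b) - margin - glength
        free_rows.extend(range(lo, hi + 1, min_anchor_gap))
    controls = []
    for mid in rng.permutation(np.array(free_rows, dtype=np.int64)):
        if len(controls) >= config.n_control_pairs:
            break
        if accept(int(mid)):
            controls.append(int(mid))
    if len(controls) < config.n_control_pairs:
        raise CohortSizingError(
            f"only {len(controls)} event-free stretches for {config.n_control_pairs} control pairs"
        )

    anchor_list = [(a, True) for a in anchors] + [(c, False) for c in controls]
    anchor_list.sort()
    gene_rows, pair_rows, expr_rows = [], [], []
    for j, (x, insulated_flag) in enumerate(anchor_list):
        strand = "+" if j % 2 == 0 else "-"
        g1 = int(rng.integers(gmin, gmax + 1))
        g2 = int(rng.integers(gmin, gmax + 1))
        left = {"gene": f"g{j:04d}_l", "chrom": "chr1", "start": x - g1 - glength, "end": x - g1, "strand": strand}
        right = {"gene": f"g{j:04d}_r", "chrom": "chr1", "start": x + g2, "end": x + g2 + glength, "strand": strand}
        gene_rows += [left, right]
        up, down = (left, right) if strand == "+" else (right, left)
        base = rng.normal(5.0, config.expression_baseline_sd)
        delta = rng.normal(0.0, config.pair_delta_sd)
        if insulated_flag:
            delta = np.sign(delta if delta != 0 else 1.0) * (
                abs(delta) + config.insulation_shift / config.n_replicates
            )
        up_vals = base + rng.normal(0.0, config.replicate_noise_sd, config.n_replicates)
        down_vals = base + delta + rng.normal(0.0, config.replicate_noise_sd, config.n_replicates)
        expr_rows.append((up["gene"], up_vals))
        expr_rows.append((down["gene"], down_vals))
        pair_rows.append(
            {
                "pair_id": f"pair_{j:04d}",
                "upstream_gene": up["gene"],
                "downstream_gene": down["gene"],
                "insulated": insulated_flag,
                "event_summit": x if insulated_flag else -1,
            }
        )
    genes = pd.DataFrame(gene_rows, columns=gene_cols)
    expression = pd.DataFrame(
        {g: v for g, v in expr_rows}, index=[f"rep{r+1}" for r in range(config.n_replicates)]
    ).T
    expression.index.name = "gene"
    pairs = pd.DataFrame(pair_rows, columns=pair_cols)
    return genes, expression, pairs


def expand_repeat_family(
    genome: np.ndarray,
    consensus: str | np.ndarray,
    n_copies: int,
    divergence_mean: float,
    seed: int | np.random.Generator,
    forbidden: pd.DataFrame | None = None,
    min_separation: int = 500,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Insert diverged copies of a consensus into a single genome.

    Standalone single-genome version of the cohort's expansion machinery:
    copies are placed at random insertion points avoiding ``forbidden``
    intervals and each other, each copy's substitutions are drawn
    independently at ``divergence_mean`` per base, and the true substitution
    count is recorded for age-estimation tests.  Returns the new genome and a
    copy table (coordinates in the *new* genome).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cons = dna.encode(consensus) if isinstance(consensus, str) else np.asarray(consensus, dtype=np.uint8)
    if n_copies < 0:
        raise ValueError("n_copies must be >= 0")
    cols = ["chrom", "start", "end", "strand", "substitutions", "consensus_length"]
    if n_copies == 0:
        return genome.copy(), pd.DataFrame(columns=cols)
    L = genome.size
    forb: list[tuple[int, int]] = []
    if forbidden is not None:
        forb = list(zip(forbidden["start"].astype(int), forbidden["end"].astype(int)))
    points: list[int] = []
    tries = 0
    while len(points) < n_copies:
        tries += 1
        if tries > n_copies * 300:
            raise CohortSizingError("insufficient free sequence for repeat insertion")
        p = int(rng.integers(0, L + 1))
        if any(s <= p < e for s, e in forb):
            continue
        if any(abs(p - q) < min_separation for q in points):
            continue
        points.append(p)
    points.sort()
    parts, rows = [], []
    prev = 0
    offset = 0
    for p in points:
        parts.append(genome[prev:p])
        copy, subs = _mutate_copy(cons, divergence_mean, rng)
        parts.append(copy)
        rows.append(
            {
                "chrom": "chr1",
                "start": p + offset,
                "end": p + offset + cons.size,
                "strand": "+",
                "substitutions": subs,
                "consensus_length": int(cons.size),
            }
        )
        offset += cons.size
        prev = p
    parts.append(genome[prev:])
    return np.concatenate(parts), pd.DataFrame(rows, columns=cols)


def aligned_windows(
    cohort: Cohort,
    anchor: str,
    centers: np.ndarray,
    strands: np.ndarray,
    halfwidth: int,
) -> np.ndarray:
    """(sites, species, width) alignment slices around anchor-species centers.

    Unalignable positions (species-specific insertions, partial projections)
    are filled with the invalid sentinel.  Rows are strand-oriented: windows
    at '-' anchors are reverse-complemented in every species.
    """
    species = cohort.species
    width = 2 * halfwidth
    n = len(centers)
    out = np.full((n, len(species), width), dna.INVALID, dtype=np.uint8)
    for i, (c, strand) in enumerate(zip(centers, strands)):
        a, b = int(c) - halfwidth, int(c) + halfwidth
        for s_idx, sp in enumerate(species):
            if sp == anchor:
                g = cohort.genomes[sp]
                if 0 <= a and b <= g.size:
                    out[i, s_idx] = g[a:b]
                continue
            pieces = cohort.block_map.project(("chr1", a, b), anchor, sp)
            if not pieces:
                continue
            if len(pieces) == 1 and pieces[0][2] - pieces[0][1] == width:
                _, ta, tb = pieces[0]
                g = cohort.genomes[sp]
                if 0 <= ta and tb <= g.size:
                    out[i, s_idx] = g[ta:tb]
        if strand == "-":
            for s_idx in range(len(species)):
                out[i, s_idx] = dna.revcomp(out[i, s_idx])
    return out
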