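"""Synthetic multi-species cohort: sequences evolved along a phylogeny with a
planted tissue-specific regulatory grammar.

Each region carries, per tissue, zero or more planted transcription-factor
motif instances; a region is "open" in a tissue for a species iff its
sequence contains matches to at least ``activity_threshold`` distinct motifs
of that tissue's set (log-odds PWM scan, threshold = consensus score minus
2 bits).  Substitutions follow Jukes-Cantor with purifying selection (a
reduced rate) on active motif instances; motif turnover is modeled as
Poisson gain (consensus insertion) and loss (instance scrambling) events on
branches.  A configurable block of regions is given a deterministic loss of
one tissue's motifs on the stem branch of one clade, planting a clean
clade-specific open-chromatin pattern.  Ortholog dropout grows with
divergence from the reference species.  Every emitted OCR call is, by
construction, the activity rule applied to the emitted sequence.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Peak, UnionPeaks
from .io import (
    ConservationTrack,
    OrthologMap,
    OrthRecord,
    write_divergence_table,
    write_fasta,
    write_peaks,
)

BASES_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_TREE = (
    "(((mouse:10,rat:10):35,hamster:45):45,"
    "((human:20,macaque:20):25,lemur:45):45);"
)
DEFAULT_CLADES = {
    "glires": ("mouse", "rat", "hamster"),
    "euarchonta": ("human", "macaque", "lemur"),
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Rates are per million years.  The default tree has six species in two
    clades with divergence times from the reference spanning 10-90 MY.
    """

    tree_newick: str = DEFAULT_TREE
    clades: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_CLADES)
    )
    reference: str = "mouse"
    n_regions: int = 2000
    region_length: int = 500
    spacer_length: int = 500
    n_chromosomes: int = 8
    gc: float = 0.41
    subs_rate: float = 0.002        # substitutions/site/MY (neutral)
    selection_factor: float = 0.05  # rate multiplier inside active motif instances
    motifs_per_tissue: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {
            "brain": ("TGACTCAG", "CAGCCAAT"),
            "liver": ("GATTACAG", "TTCGAACC"),
        }
    )
    pwm_consensus_p: float = 0.55   # match threshold then tolerates 1 mismatch
    activity_threshold: int = 2     # distinct motifs required for "open"
    copies_per_motif: int = 2       # planted instances per motif family
    p_open_root: float = 0.35
    gain_rate: float = 0.001        # per motif per region per MY
    loss_rate: float = 0.0015       # per active instance per MY
    clade_loss_tissue: str = "brain"
    clade_loss_clade: str = "euarchonta"
    n_clade_loss: int = 150         # planted clade-specific-loss block size
    dropout_rate_per_my: float = 0.003
    dropout_max: float = 0.5
    # closest assayed relative per species; sister-pair outgroups are
    # equidistant from both sister taxa, so the choice must be explicit
    neighbors: Mapping[str, str] = field(
        default_factory=lambda: {
            "mouse": "rat", "rat": "mouse", "hamster": "mouse",
            "human": "macaque", "macaque": "human", "lemur": "human",
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subs_rate", "gain_rate", "loss_rate", "dropout_rate_per_my"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.activity_threshold < 1:
            raise ValueError("activity_threshold must be >= 1")


def pwm_from_consensus(consensus: str, p_consensus: float) -> np.ndarray:
    """(width, 4) probability matrix concentrated on the consensus base."""
    idx = {b: i for i, b in enumerate("ACGT")}
    w = len(consensus)
    pwm = np.full((w, 4), (1.0 - p_consensus) / 3.0)
    for j, b in enumerate(consensus):
        pwm[j, idx[b]] = p_consensus
    return pwm


def pwm_log_odds(pwm: np.ndarray, background: float = 0.25) -> np.ndarray:
    return np.log2(pwm / background)


def pwm_match_threshold(pwm: np.ndarray, margin_bits: float = 2.0) -> float:
    """Consensus log-odds score minus ``margin_bits``."""
    lom = pwm_log_odds(pwm)
    return float(lom.max(axis=1).sum() - margin_bits)


def scan_scores(arr: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Log-odds score at every window start of an integer-coded sequence."""
    w = lom.shape[0]
    n = len(arr) - w + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for j in range(w):
        scores += lom[j][arr[j : j + n]]
    return scores


@dataclass
class _Instance:
    region: int
    tissue: str
    motif: int
    chrom: str
    pos: int          # absolute start on the chromosome
    active: bool = True
    protected: bool = False  # planted clade-loss block: exempt from turnover


@dataclass
class _NodeState:
    seqs: dict
    instances: list


class SimulatedCohort:
    """In-memory cohort: sequences, calls, ortholog map, tracks, truth."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.species: list[str] = []
        self.sequences: dict[str, dict[str, np.ndarray]] = {}
        self.root_sequences: dict[str, np.ndarray] = {}
        self.regions: pd.DataFrame = pd.DataFrame()
        self.labels: dict[str, pd.DataFrame] = {}
        self.usable: pd.DataFrame = pd.DataFrame()
        self.divergence: dict[str, float] = {}
        self.ortholog_map: OrthologMap = OrthologMap()
        self.conservation: ConservationTrack = ConservationTrack()
        self.block_region_ids: list[str] = []
        self.tree = None

    # -- sequence access ----------------------------------------------------

    def seq_str(self, species: str, chrom: str, start: int = 0, end: Optional[int] = None) -> str:
        arr = self.sequences[species][chrom]
        end = len(arr) if end is None else end
        return BASES_ARR[arr[start:end]].tobytes().decode()

    def window_array(self, species: str, region_id: str, flank: Optional[int] = None) -> np.ndarray:
        row = self.regions.loc[region_id]
        if flank is None:
            start, end = row.start, row.end
        else:
            start, end = row.summit - flank, row.summit + flank
        return self.sequences[species][row.chrom][start:end]

    def window_seq(self, species: str, region_id: str, flank: Optional[int] = None) -> str:
        return BASES_ARR[self.window_array(species, region_id, flank)].tobytes().decode()

    def window_onehot(self, species: str, region_id: str) -> np.ndarray:
        return np.eye(4, dtype=np.float32)[self.window_array(species, region_id)]

    # -- peak calls ---------------------------------------------------------

    def peaks_for(self, species: str, tissue: str, usable_only: bool = False) -> list[Peak]:
        lab = self.labels[tissue][species]
        out = []
        for rid, open_ in lab.items():
            if not open_:
                continue
            if usable_only and not self.usable.loc[rid, species]:
                continue
            row = self.regions.loc[rid]
            out.append(
                Peak(
                    interval=GenomicInterval(species, row.chrom, int(row.start), int(row.end)),
                    summit=int(row.summit),
                    tissue=tissue,
                    dataset_id=f"{species}_{tissue}_ds1",
                    name=rid,
                )
            )
        return out

    def union_pooled(self, species: str, tissue: str) -> UnionPeaks:
        return UnionPeaks.from_peaks(
            [self.peaks_for(species, tissue)], species=species, tissue=tissue
        )

    def dataset_pooled(self, species: str, tissue: str) -> list[UnionPeaks]:
        # one dataset per species/tissue in the simulated design
        return [self.union_pooled(species, tissue)]

    # -- serialization ------------------------------------------------------

    def write(self, outdir) -> None:
        """Write the formats the pipeline reads; byte-identical under a seed."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for sp in self.species:
            write_fasta(
                {c: self.seq_str(sp, c) for c in sorted(self.sequences[sp])},
                out / f"{sp}.fa",
            )
            for tissue in self.labels:
                write_peaks(
                    self.peaks_for(sp, tissue), out / f"{sp}_{tissue}.narrowPeak"
                )
        self.ortholog_map.write_tsv(out / "orthologs.tsv")
        write_divergence_table(self.divergence, out / "divergence.tsv")
        self.conservation.write_bedgraph(out / "conservation.bedGraph")
        (out / "tree.nwk").write_text(self.config.tree_newick + "\n")
        for tissue, lab in self.labels.items():
            lab.astype(int).to_csv(out / f"labels_{tissue}.tsv", sep="\t")
        self.usable.astype(int).to_csv(out / "usable_orthologs.tsv", sep="\t")


def simulate_cohort(config: Optional[SimConfig] = None, seed: Optional[int] = None) -> SimulatedCohort:
    """Generate a cohort under ``config`` (deterministic for a given seed)."""
    import dendropy

    cfg = copy.deepcopy(config) if config is not None else SimConfig()
    if seed is not None:
        cfg.seed = seed
    rng = np.random.default_rng(cfg.seed)

    try:
        tree = dendropy.Tree.get(data=cfg.tree_newick, schema="newick")
    except Exception as exc:
        raise ValueError(f"unreadable newick tree: {exc}") from exc
    tree.is_rooted = True

    cohort = SimulatedCohort(cfg)
    cohort.tree = tree
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    cohort.species = leaves
    if cfg.reference not in leaves:
        raise ValueError(f"reference {cfg.reference!r} not a leaf of the tree")

    # region layout: round-robin over chromosomes, fixed slot stride
    rl, sl = cfg.region_length, cfg.spacer_length
    stride = rl + sl
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    rows = []
    for i in range(cfg.n_regions):
        chrom = chrom_names[i % cfg.n_chromosomes]
        slot = i // cfg.n_chromosomes
        start = sl + slot * stride
        rows.append((f"r{i:05d}", chrom, start, start + rl, start + rl // 2))
    regions = pd.DataFrame(
        rows, columns=["region_id", "chrom", "start", "end", "summit"]
    ).set_index("region_id", drop=False)
    cohort.regions = regions
    n_per_chrom = {
        c: int((regions.chrom == c).sum()) for c in chrom_names
    }
    chrom_len = {c: sl + n_per_chrom[c] * stride for c in chrom_names}

    # root sequences
    gc = cfg.gc
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    root_seqs = {
        c: rng.choice(4, size=chrom_len[c], p=base_p).astype(np.uint8)
        for c in chrom_names
    }

    pwms = {
        t: [pwm_from_consensus(m, cfg.pwm_consensus_p) for m in motifs]
        for t, motifs in cfg.motifs_per_tissue.items()
    }
    consensi_int = {
        t: [np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in m], np.uint8)
            for m in motifs]
        for t, motifs in cfg.motifs_per_tissue.items()
    }

    # planted clade-loss block + root open/closed assignment
    tissues = list(cfg.motifs_per_tissue)
    block = set(range(min(cfg.n_clade_loss, cfg.n_regions)))
    cohort.block_region_ids = [f"r{i:05d}" for i in sorted(block)]
    open_at_root = {
        t: rng.random(cfg.n_regions) < cfg.p_open_root for t in tissues
    }
    if cfg.n_clade_loss > 0:
        open_at_root[cfg.clade_loss_tissue][list(block)] = True

    instances: list[_Instance] = []
    for i in range(cfg.n_regions):
        row = regions.iloc[i]
        for t in tissues:
            if not open_at_root[t][i]:
                continue
            protected = t == cfg.clade_loss_tissue and i in block
            taken: list[tuple[int, int]] = []
            for mi, cons in enumerate(consensi_int[t]):
                w = len(cons)
                for _copy in range(cfg.copies_per_motif):
                    for _ in range(30):
                        off = int(rng.integers(5, rl - w - 5))
                        if all(off + w <= s or off >= s + wlen for s, wlen in taken):
                            break
                    taken.append((off, w))
                    pos = int(row.start) + off
                    root_seqs[row.chrom][pos : pos + w] = cons
                    instances.append(
                        _Instance(region=i, tissue=t, motif=mi, chrom=row.chrom,
                                  pos=pos, protected=protected)
                    )
    cohort.root_sequences = {c: a.copy() for c, a in root_seqs.items()}

    # identify the stem edge of the clade with the planted loss
    loss_clade_species = set(cfg.clades.get(cfg.clade_loss_clade, ()))
    taxa = {t.label: t for t in tree.taxon_namespace}
    stem_node = None
    if loss_clade_species and cfg.n_clade_loss > 0:
        stem_node = tree.mrca(taxa=[taxa[s] for s in loss_clade_species])

    # evolve down the tree (preorder, deterministic traversal under one rng)
    leaf_states: dict[str, _NodeState] = {}

    def evolve(node, state: _NodeState) -> None:
        for child in node.child_nodes():
            t_my = child.edge.length or 0.0
            child_state = _evolve_branch(
                state, t_my, rng, cfg, regions,
                force_block_loss=(child is stem_node),
                block=block,
            )
            if child.is_leaf():
                leaf_states[child.taxon.label] = child_state
            else:
                evolve(child, child_state)

    root_state = _NodeState(seqs=root_seqs, instances=instances)
    evolve(tree.seed_node, root_state)

    cohort.sequences = {sp: st.seqs for sp, st in leaf_states.items()}

    # labels from the activity rule applied to each emitted sequence
    loms = {
        t: [pwm_log_odds(p) for p in pwms[t]] for t in tissues
    }
    thresholds = {
        t: [pwm_match_threshold(p) for p in pwms[t]] for t in tissues
    }
    starts_by_chrom = {
        c: regions.loc[regions.chrom == c, "start"].to_numpy() for c in chrom_names
    }
    ids_by_chrom = {
        c: regions.loc[regions.chrom == c, "region_id"].tolist() for c in chrom_names
    }
    for t in tissues:
        lab = pd.DataFrame(False, index=regions.index, columns=leaves)
        for sp in leaves:
            for c in chrom_names:
                starts = starts_by_chrom[c]
                if len(starts) == 0:
                    continue
                n_match = np.zeros(len(starts), dtype=int)
                for lom, thr in zip(loms[t], thresholds[t]):
                    sc = scan_scores(cohort.sequences[sp][c], lom)
                    hit = sc >= thr
                    w = lom.shape[0]
                    csum = np.concatenate(([0], np.cumsum(hit)))
                    lo = starts
                    hi = starts + rl - w + 1
                    n_match += (csum[hi] - csum[lo]) > 0
                lab.loc[ids_by_chrom[c], sp] = n_match >= cfg.activity_threshold
        cohort.labels[t] = lab

    # divergence times (ultrametric tree: half the patristic distance)
    pdm = tree.phylogenetic_distance_matrix()
    ref_taxon = taxa[cfg.reference]
    cohort.divergence = {
        sp: float(pdm.patristic_distance(ref_taxon, taxa[sp])) / 2.0 for sp in leaves
    }

    # ortholog dropout, increasing with divergence from the reference
    usable = pd.DataFrame(True, index=regions.index, columns=leaves)
    for sp in leaves:
        if sp == cfg.reference:
            continue
        p_drop = min(cfg.dropout_max, cfg.dropout_rate_per_my * cohort.divergence[sp])
        usable[sp] = rng.random(cfg.n_regions) >= p_drop
    cohort.usable = usable

    # ortholog map: identical coordinates across species (no indels simulated)
    omap = OrthologMap()
    usable_np = usable.to_numpy()
    sp_index = {sp: j for j, sp in enumerate(leaves)}
    for i, row in enumerate(regions.itertuples(index=False)):
        for s in leaves:
            if not usable_np[i, sp_index[s]]:
                continue
            for tgt in leaves:
                if tgt == s or not usable_np[i, sp_index[tgt]]:
                    continue
                omap.add(
                    s, row.region_id, tgt,
                    OrthRecord(
                        GenomicInterval(tgt, row.chrom, int(row.start), int(row.end)),
                        int(row.summit),
                    ),
                )
    cohort.ortholog_map = omap

    # stand-in conservation score: fraction of species matching the root base
    per_chrom = {}
    for c in chrom_names:
        match = np.zeros(chrom_len[c])
        for sp in leaves:
            match += cohort.sequences[sp][c] == cohort.root_sequences[c]
        per_chrom[c] = np.round(match / len(leaves), 6)
    cohort.conservation = ConservationTrack.from_arrays(per_chrom)
    return cohort


def _evolve_branch(
    state: _NodeState,
    t_my: float,
    rng: np.random.Generator,
    cfg: SimConfig,
    regions: pd.DataFrame,
    force_block_loss: bool,
    block: set,
) -> _NodeState:
    seqs = {c: a.copy() for c, a in state.seqs.items()}
    instances = [copy.copy(inst) for inst in state.instances]

    # purifying selection: reduced substitution rate inside active instances
    protected_mask = {c: np.zeros(len(a), dtype=bool) for c, a in seqs.items()}
    for inst in instances:
        if inst.active:
            w = len(cfg.motifs_per_tissue[inst.tissue][inst.motif])
            protected_mask[inst.chrom][inst.pos : inst.pos + w] = True

    p_norm = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * cfg.subs_rate * t_my))
    p_prot = 0.75 * (
        1.0 - np.exp(-4.0 / 3.0 * cfg.subs_rate * cfg.selection_factor * t_my)
    )
    for c, arr in seqs.items():
        p_site = np.where(protected_mask[c], p_prot, p_norm)
        hit = rng.random(len(arr)) < p_site
        n_hit = int(hit.sum())
        if n_hit:
            arr[hit] = (arr[hit] + rng.integers(1, 4, n_hit).astype(np.uint8)) % 4

    # stochastic motif loss: a loss event removes a whole motif family (all
    # active copies in the region), so the region loses that distinct motif;
    # the planted block is exempt
    p_loss = 1.0 - np.exp(-cfg.loss_rate * t_my)
    families: dict[tuple, list[_Instance]] = {}
    for inst in instances:
        if inst.active and not inst.protected:
            families.setdefault((inst.region, inst.tissue, inst.motif), []).append(inst)
    for key in sorted(families):
        if rng.random() < p_loss:
            for inst in families[key]:
                _scramble(seqs[inst.chrom], inst, cfg, rng)
                inst.active = False

    # deterministic clade loss on the stem branch of the planted clade
    if force_block_loss:
        for inst in instances:
            if (
                inst.active
                and inst.protected
                and inst.tissue == cfg.clade_loss_tissue
                and inst.region in block
            ):
                _scramble(seqs[inst.chrom], inst, cfg, rng)
                inst.active = False
                inst.protected = False

    # stochastic motif gain (consensus insertion); block regions exempt for
    # the planted tissue so the clade pattern stays clean
    p_gain = 1.0 - np.exp(-cfg.gain_rate * t_my)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    rl = cfg.region_length
    for i, row in enumerate(regions.itertuples(index=False)):
        for t, motifs in cfg.motifs_per_tissue.items():
            if t == cfg.clade_loss_tissue and i in block:
                continue
            for mi, motif in enumerate(motifs):
                if rng.random() < p_gain:
                    w = len(motif)
                    off = int(rng.integers(5, rl - w - 5))
                    pos = int(row.start) + off
                    seqs[row.chrom][pos : pos + w] = np.array(
                        [idx[b] for b in motif], np.uint8
                    )
                    instances.append(
                        _Instance(region=i, tissue=t, motif=mi, chrom=row.chrom, pos=pos)
                    )
    return _NodeState(seqs=seqs, instances=instances)


def _scramble(arr: np.ndarray, inst: _Instance, cfg: SimConfig, rng: np.random.Generator):
    w = len(cfg.motifs_per_tissue[inst.tissue][inst.motif])
    window = arr[inst.pos : inst.pos + w]
    arr[inst.pos : inst.pos + w] = window[rng.permutation(w)]


# ---------------------------------------------------------------------------
# planted ground truth
# ---------------------------------------------------------------------------

def planted_truth(cohort: SimulatedCohort, tissue: str) -> dict:
    """Ground-truth analogues of the evaluation sets, from the label matrix.

    clade_specific[c]: regions open in every species of clade c and closed in
    every other species.  species_specific[s]: regions open in s and closed
    in its single closest relative.  Also reports per-species-pair divergent
    label fractions.
    """
    lab = cohort.labels[tissue]
    cfg = cohort.config
    clades = {c: [s for s in sps if s in lab.columns] for c, sps in cfg.clades.items()}

    clade_specific = {}
    for c, members in clades.items():
        others = [s for cc, sps in clades.items() if cc != c for s in sps]
        mask = lab[members].all(axis=1) & (~lab[others]).all(axis=1)
        clade_specific[c] = set(lab.index[mask])

    from .evaluation import closest_species

    species_specific = {}
    for sp in lab.columns:
        nb = cfg.neighbors.get(sp) or closest_species(cohort.tree, sp, list(lab.columns))
        mask = lab[sp] & ~lab[nb]
        species_specific[sp] = set(lab.index[mask])

    pair_divergence = {}
    for a in lab.columns:
        for b in lab.columns:
            if a < b:
                pair_divergence[(a, b)] = float((lab[a] != lab[b]).mean())
    return {
        "clade_specific": clade_specific,
        "species_specific": species_specific,
        "pair_divergent_fraction": pair_divergence,
    }
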