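"""Forward simulator of polyploid genome evolution with known ground truth.

The simulator evolves an ancestral gene order along an event tree of
speciations, whole-genome duplications (WGDs) and allopolyploid mergers,
applying per-copy gene loss (fractionation) after each WGD, tandem
duplication, and chromosome rearrangements.  It emits per-genome gene
annotations, fabricated all-vs-all homology hits whose percent identity
decays with divergence time, and a truth table recording, for every
surviving homologous gene pair, the event that separated it.

Time is measured in abstract divergence units (larger = older); only the
ordering of events matters downstream.  The ``poaceae9`` preset mirrors the
nine-genome grass panel: a rice-like reference and five further diploids
sharing one ancient tetraploidization, a maize-like genome with an extra
lineage WGD, and a wheat-like hexaploid merging three diverged diploid
lineages (subgenomes A/B/D).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .model import Gene, GenomeAnnotation

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# event tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Event:
    id: str
    kind: str  # "speciation" | "wgd" | "allopolyploid_merge" | "tandem"
    time: float


@dataclass
class TreeNode:
    """A node of the speciation tree.

    ``time`` is the divergence time for internal nodes and 0 for tips;
    ``branch_wgds`` are WGD events on the branch *above* this node, each
    older than ``time`` and younger than the parent's time.
    """

    name: str
    time: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    branch_wgds: list[Event] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass(frozen=True)
class Merge:
    """An allopolyploidization: donor tip lineages fuse into one genome."""

    event: Event
    genome_id: str
    donors: tuple[tuple[str, str], ...]  # (subgenome_label, donor tip name)


@dataclass
class EventTree:
    """Speciation tree plus WGD and merger events; validated on creation."""

    root: TreeNode
    merges: list[Merge] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        names: set[str] = set()

        def walk(node: TreeNode, parent_time: float | None) -> None:
            if node.name in names:
                raise ValueError(f"duplicate node name {node.name!r}")
            names.add(node.name)
            if parent_time is not None and node.time >= parent_time:
                raise ValueError(
                    f"node {node.name!r}: time {node.time} not younger than "
                    f"parent time {parent_time}"
                )
            upper = parent_time if parent_time is not None else float("inf")
            for w in node.branch_wgds:
                if w.kind != "wgd":
                    raise ValueError(f"branch event {w.id!r} is not a wgd")
                if not (node.time < w.time < upper):
                    raise ValueError(
                        f"wgd {w.id!r} at time {w.time} outside branch interval "
                        f"({node.time}, {upper}) above node {node.name!r}"
                    )
            if node.is_tip and node.time != 0:
                raise ValueError(f"tip {node.name!r} must have time 0")
            if len(node.children) == 1:
                raise ValueError(f"node {node.name!r} has a single child")
            for c in node.children:
                walk(c, node.time)

        walk(self.root, None)
        tipset = set(self.tip_names())
        consumed: set[str] = set()
        for m in self.merges:
            if m.event.kind != "allopolyploid_merge":
                raise ValueError(f"merge event {m.event.id!r} has wrong kind")
            if len(m.donors) < 2:
                raise ValueError(
                    f"merge {m.event.id!r} must combine >= 2 lineages"
                )
            for label, donor in m.donors:
                if donor not in tipset:
                    raise ValueError(f"merge donor {donor!r} is not a tip")
                if donor in consumed:
                    raise ValueError(f"tip {donor!r} consumed by two merges")
                consumed.add(donor)
                pt = self._parent_time(donor)
                if m.event.time >= pt:
                    raise ValueError(
                        f"merge {m.event.id!r} at time {m.event.time} is older "
                        f"than the divergence ({pt}) of its donor {donor!r}"
                    )

    def _parent_time(self, tip: str) -> float:
        def walk(node: TreeNode) -> float | None:
            for c in node.children:
                if c.name == tip:
                    return node.time
                t = walk(c)
                if t is not None:
                    return t
            return None

        t = walk(self.root)
        if t is None:
            raise ValueError(f"tip {tip!r} not found")
        return t

    # -- queries --------------------------------------------------------------

    def tip_names(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_tip:
                out.append(node.name)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def genome_ids(self) -> list[str]:
        """Final genome ids in deterministic (tree traversal) order.

        A merged polyploid appears at the position of its first donor tip;
        consumed donor tips are dropped.
        """
        merged_at = {m.donors[0][1]: m.genome_id for m in self.merges}
        consumed = {d for m in self.merges for _, d in m.donors}
        out: list[str] = []
        for tip in self.tip_names():
            if tip in merged_at:
                out.append(merged_at[tip])
            elif tip not in consumed:
                out.append(tip)
        return out

    def merge_for(self, genome_id: str) -> Merge | None:
        for m in self.merges:
            if m.genome_id == genome_id:
                return m
        return None

    def _path_to(self, tip: str) -> list[TreeNode]:
        path: list[TreeNode] = []

        def walk(node: TreeNode) -> bool:
            path.append(node)
            if node.name == tip:
                return True
            for c in node.children:
                if walk(c):
                    return True
            path.pop()
            return False

        if not walk(self.root):
            raise ValueError(f"tip {tip!r} not found")
        return path

    def wgds_on_lineage(self, tip: str) -> list[Event]:
        """All WGD events on the root-to-tip path (root-branch WGDs included)."""
        return [w for node in self._path_to(tip) for w in node.branch_wgds]

    def has_root_wgd(self) -> bool:
        return bool(self.root.branch_wgds)

    def speciation_between(self, tip_a: str, tip_b: str) -> Event:
        """The speciation event (MRCA) separating two tips."""
        pa, pb = self._path_to(tip_a), self._path_to(tip_b)
        mrca = None
        for x, y in zip(pa, pb):
            if x is y:
                mrca = x
            else:
                break
        if mrca is None or mrca.is_tip:
            raise ValueError(f"{tip_a!r} and {tip_b!r} share no speciation")
        return Event(mrca.name, "speciation", mrca.time)

    def events(self) -> dict[str, Event]:
        out: dict[str, Event] = {}

        def walk(node: TreeNode) -> None:
            if not node.is_tip:
                out[node.name] = Event(node.name, "speciation", node.time)
            for w in node.branch_wgds:
                out[w.id] = w
            for c in node.children:
                walk(c)

        walk(self.root)
        for m in self.merges:
            out[m.event.id] = m.event
        return out


def poaceae9_tree() -> EventTree:
    """Nine-genome grass-like preset.

    One root WGD ("gct") shared by all lineages, an extra WGD ("mst") on the
    maize-like lineage, and a three-way allohexaploidization ("hexaploid")
    merging the A/B/D donor lineages into the wheat-like genome.  Times are
    abstract placeholders chosen to respect the known event ordering
    (root WGD > speciations > lineage WGD / hexaploidization); see the
    methods note.
    """
    tip = TreeNode
    adc = TreeNode("split_AD", 15.0, [
        TreeNode("split_A", 8.0, [tip("t_urartu"), tip("wheat_A")]),
        TreeNode("split_D", 8.0, [tip("ae_tauschii"), tip("wheat_D")]),
    ])
    triticeae = TreeNode("split_B", 20.0, [tip("wheat_B"), adc])
    pooideae = TreeNode("split_barley", 35.0, [tip("barley"), triticeae])
    bep_core = TreeNode("split_brachy", 45.0, [tip("brachypodium"), pooideae])
    bep = TreeNode("split_rice", 60.0, [tip("rice"), bep_core])
    maize = TreeNode("maize", 0.0, branch_wgds=[Event("mst", "wgd", 25.0)])
    pacmad_core = TreeNode("split_sorghum", 40.0, [tip("sorghum"), maize])
    pacmad = TreeNode("split_millet", 50.0, [tip("millet"), pacmad_core])
    root = TreeNode(
        "root", 70.0, [bep, pacmad], branch_wgds=[Event("gct", "wgd", 100.0)]
    )
    merge = Merge(
        Event("hexaploid", "allopolyploid_merge", 2.0),
        "wheat",
        (("A", "wheat_A"), ("B", "wheat_B"), ("D", "wheat_D")),
    )
    return EventTree(root=root, merges=[merge])


def build_event_tree(preset_or_spec: str | dict) -> EventTree:
    """Build a validated event tree from a preset name or a dict spec.

    The dict spec mirrors the YAML layout::

        topology:
          name: root
          time: 70
          wgds: [{id: gct, time: 100}]
          children:
            - {name: a}
            - {name: b}
        merges:
          - {id: hex, time: 2, genome: wheat, donors: {A: tip1, B: tip2}}
    """
    if isinstance(preset_or_spec, str):
        if preset_or_spec == "poaceae9":
            return poaceae9_tree()
        raise ValueError(f"unknown preset {preset_or_spec!r}")

    def build(d: dict) -> TreeNode:
        return TreeNode(
            name=d["name"],
            time=float(d.get("time", 0.0)),
            children=[build(c) for c in d.get("children", [])],
            branch_wgds=[
                Event(w["id"], "wgd", float(w["time"]))
                for w in d.get("wgds", [])
            ],
        )

    merges = [
        Merge(
            Event(m["id"], "allopolyploid_merge", float(m["time"])),
            m["genome"],
            tuple(sorted(m["donors"].items())),
        )
        for m in preset_or_spec.get("merges", [])
    ]
    return EventTree(root=build(preset_or_spec["topology"]), merges=merges)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Simulation parameters.

    loss_rate_per_copy
        probability that each gene copy is lost in the fractionation episode
        immediately following a WGD (applied independently per copy, so a
        duplicate pair survives intact with probability (1-f)^2).
    tandem_rate
        per-gene probability of spawning an adjacent tandem copy on each
        branch of the tree.
    inversion_rate / translocation_rate
        expected number of the respective rearrangements per branch
        (Poisson-distributed counts).
    fission_count / fission_genome / fission_chromosome
        plant this many chromosome fissions on the terminal branch of the
        named genome (largest chromosome unless one is named).
    similarity_decay
        k in identity = 100 * exp(-k * t) for a pair separated at time t.
    identity_noise_sd
        Gaussian noise (percent identity) added per homologous pair.
    spurious_fraction
        number of random non-homologous hits to fabricate, as a fraction of
        the number of true pairs; their identity ~ Uniform(20, 50).
    """

    n_ancestral_genes: int = 500
    n_chromosomes: int = 4
    loss_rate_per_copy: float = 0.3
    tandem_rate: float = 0.02
    inversion_rate: float = 0.2
    translocation_rate: float = 0.1
    fission_count: int = 0
    fission_genome: str | None = None
    fission_chromosome: str | None = None
    similarity_decay: float = 0.005
    identity_noise_sd: float = 3.0
    spurious_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ancestral_genes < 1:
            raise ValueError("n_ancestral_genes must be >= 1")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        for name in ("loss_rate_per_copy", "tandem_rate", "spurious_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.identity_noise_sd < 0:
            raise ValueError("identity_noise_sd must be >= 0")
        if self.similarity_decay < 0:
            raise ValueError("similarity_decay must be >= 0")


class Copy(NamedTuple):
    """A surviving gene copy: ancestral family plus its event path.

    ``path`` lists (event_id, side) pairs in chronological order; two copies
    diverged at the first event where their paths differ.
    """

    family: int
    uid: int
    path: tuple[tuple[str, int], ...]


Chromosomes = dict[str, list[Copy]]


@dataclass
class SimulationResult:
    tree: EventTree
    config: SimulationConfig
    annotations: dict[str, GenomeAnnotation]
    truth: pd.DataFrame  # gene_a, gene_b, event_id, relation, divergence_time
    #: genomes whose gene count dropped to zero under extreme loss
    empty_genomes: list[str] = field(default_factory=list)
    #: subgenome label by chromosome prefix for merged genomes
    subgenomes: dict[str, dict[str, str]] = field(default_factory=dict)


TRUTH_COLUMNS = ["gene_a", "gene_b", "event_id", "relation", "divergence_time"]


class _Simulator:
    def __init__(self, tree: EventTree, config: SimulationConfig) -> None:
        self.tree = tree
        self.cfg = config
        root_seq = np.random.SeedSequence(config.seed)
        evolve_seq, hits_seq = root_seq.spawn(2)
        self.rng = np.random.default_rng(evolve_seq)
        self.hits_rng = np.random.default_rng(hits_seq)
        self.uid = 0
        self.event_times: dict[str, Event] = tree.events()
        self.tip_states: dict[str, Chromosomes] = {}

    def _next_uid(self) -> int:
        self.uid += 1
        return self.uid

    # -- evolution primitives -------------------------------------------------

    def _ancestral(self) -> Chromosomes:
        n, k = self.cfg.n_ancestral_genes, self.cfg.n_chromosomes
        sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
        chroms: Chromosomes = {}
        fam = 0
        for i, size in enumerate(sizes, start=1):
            genes = []
            for _ in range(size):
                genes.append(Copy(fam, self._next_uid(), ()))
                fam += 1
            chroms[f"c{i}"] = genes
        return chroms

    def _wgd(self, state: Chromosomes, event: Event) -> Chromosomes:
        out: Chromosomes = {}
        for chrom, genes in state.items():
            out[chrom] = [
                Copy(g.family, self._next_uid(), g.path + ((event.id, 0),))
                for g in genes
            ]
        for chrom, genes in state.items():
            out[f"{chrom}-{event.id}"] = [
                Copy(g.family, self._next_uid(), g.path + ((event.id, 1),))
                for g in genes
            ]
        return out

    def _fractionate(self, state: Chromosomes) -> Chromosomes:
        f = self.cfg.loss_rate_per_copy
        if f == 0:
            return state
        out: Chromosomes = {}
        for chrom, genes in state.items():
            keep = self.rng.random(len(genes)) >= f
            out[chrom] = [g for g, k in zip(genes, keep) if k]
        return out

    def _tandems(self, state: Chromosomes, branch_time: float) -> Chromosomes:
        rate = self.cfg.tandem_rate
        if rate == 0:
            return state
        out: Chromosomes = {}
        for chrom, genes in state.items():
            new: list[Copy] = []
            dup = self.rng.random(len(genes)) < rate
            for g, d in zip(genes, dup):
                new.append(g)
                if d:
                    uid = self._next_uid()
                    ev = Event(f"tandem{uid}", "tandem", branch_time)
                    self.event_times[ev.id] = ev
                    new.append(Copy(g.family, uid, g.path + ((ev.id, 1),)))
            out[chrom] = new
        return out

    def _branch_to(self, node: TreeNode, side: int, parent_name: str,
                   state: Chromosomes) -> Chromosomes:
        return {
            chrom: [
                Copy(g.family, self._next_uid(), g.path + ((parent_name, side),))
                for g in genes
            ]
            for chrom, genes in state.items()
        }

    # -- rearrangements --------------------------------------------------------

    def _rearrange(self, state: Chromosomes, tip_name: str | None) -> Chromosomes:
        state = dict(state)
        n_inv = int(self.rng.poisson(self.cfg.inversion_rate))
        for _ in range(n_inv):
            apply_inversion(state, self.rng)
        n_tra = int(self.rng.poisson(self.cfg.translocation_rate))
        for _ in range(n_tra):
            apply_translocation(state, self.rng)
        if tip_name is not None and self.cfg.fission_genome == tip_name:
            for _ in range(self.cfg.fission_count):
                apply_fission(state, self.rng, self.cfg.fission_chromosome)
        return state

    # -- traversal -------------------------------------------------------------

    def run(self) -> None:
        state = self._ancestral()
        self._descend(self.tree.root, None, state)

    def _descend(self, node: TreeNode, parent_time: float | None,
                 state: Chromosomes) -> None:
        for wgd in sorted(node.branch_wgds, key=lambda e: -e.time):
            state = self._wgd(state, wgd)
            state = self._fractionate(state)
        branch_mid = (parent_time + node.time) / 2 if parent_time is not None \
            else node.time + 1.0
        if parent_time is not None or node.branch_wgds:
            state = self._tandems(state, branch_mid)
            state = self._rearrange(state, node.name if node.is_tip else None)
        if node.is_tip:
            self.tip_states[node.name] = state
            return
        for side, child in enumerate(node.children):
            self._descend(child, node.time, self._branch_to(
                child, side, node.name, state))

    # -- emission --------------------------------------------------------------

    def finalize(self) -> SimulationResult:
        consumed = {d for m in self.tree.merges for _, d in m.donors}
        genome_states: dict[str, Chromosomes] = {}
        subgenomes: dict[str, dict[str, str]] = {}
        for tip, state in self.tip_states.items():
            if tip not in consumed:
                genome_states[tip] = state
        for m in self.tree.merges:
            merged: Chromosomes = {}
            labels: dict[str, str] = {}
            for label, donor in m.donors:
                for chrom, genes in self.tip_states[donor].items():
                    merged[f"{label}.{chrom}"] = genes
                    labels[label] = label
            genome_states[m.genome_id] = merged
            subgenomes[m.genome_id] = labels
        # deterministic genome order from the tree
        ordered = {g: genome_states[g] for g in self.tree.genome_ids()}

        annotations: dict[str, GenomeAnnotation] = {}
        copy_gene: dict[int, tuple[str, str]] = {}  # uid -> (genome, gene_id)
        families: dict[int, list[tuple[str, Copy]]] = {}
        empty: list[str] = []
        for genome, state in ordered.items():
            genes: list[Gene] = []
            for chrom in sorted(state):
                for pos, copy in enumerate(state[chrom], start=1):
                    gid = f"{genome}_g{copy.family:04d}_{copy.uid:06d}"
                    start = (pos - 1) * 1000 + 1
                    strand = "+" if self.rng.random() < 0.5 else "-"
                    genes.append(
                        Gene(gid, genome, chrom, 0, start, start + 599, strand)
                    )
                    copy_gene[copy.uid] = (genome, gid)
                    families.setdefault(copy.family, []).append((gid, copy))
            if not genes:
                warnings.warn(f"genome {genome!r} lost all genes")
                empty.append(genome)
                annotations[genome] = GenomeAnnotation(genome, {})
            else:
                annotations[genome] = GenomeAnnotation.from_genes(genome, genes)

        truth = self._truth_table(families, copy_gene)
        return SimulationResult(
            tree=self.tree, config=self.cfg, annotations=annotations,
            truth=truth, empty_genomes=empty, subgenomes=subgenomes,
        )

    def _divergence(self, a: Copy, b: Copy) -> Event:
        pa, pb = a.path, b.path
        for (ea, sa), (eb, sb) in zip(pa, pb):
            if ea == eb:
                if sa != sb:
                    return self.event_times[ea]
            else:
                ta, tb = self.event_times[ea].time, self.event_times[eb].time
                return self.event_times[ea] if ta >= tb else self.event_times[eb]
        longer = pa if len(pa) > len(pb) else pb
        return self.event_times[longer[min(len(pa), len(pb))][0]]

    def _truth_table(
        self,
        families: dict[int, list[tuple[str, Copy]]],
        copy_gene: dict[int, tuple[str, str]],
    ) -> pd.DataFrame:
        rows = []
        for fam in sorted(families):
            members = families[fam]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    gid_a, ca = members[i]
                    gid_b, cb = members[j]
                    ev = self._divergence(ca, cb)
                    genome_a = copy_gene[ca.uid][0]
                    genome_b = copy_gene[cb.uid][0]
                    if ev.kind == "speciation":
                        relation = "homoeolog" if genome_a == genome_b else "ortholog"
                    elif ev.kind == "wgd":
                        relation = f"{ev.id}_paralog"
                    elif ev.kind == "tandem":
                        relation = "tandem"
                    else:  # pragma: no cover
                        relation = "unassigned"
                    a_id, b_id = sorted((gid_a, gid_b))
                    rows.append((a_id, b_id, ev.id, relation, ev.time))
        df = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
        return df.sort_values(["gene_a", "gene_b"], kind="mergesort").reset_index(
            drop=True
        )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def evolve_genomes(
    tree: EventTree, config: SimulationConfig
) -> SimulationResult:
    """Simulate the tree and return annotations plus the truth table."""
    sim = _Simulator(tree, config)
    sim.run()
    return sim.finalize()


def emit_hits(result: SimulationResult) -> pd.DataFrame:
    """Fabricate an all-vs-all homology hit table from the truth table.

    Each true pair gets identity = 100 exp(-k t) + N(0, sd) clipped to
    (0, 100]; the E-value is a fixed monotone function of identity
    (10^(4 - 0.3 * identity)) and the bitscore is 2 * identity.  Random
    spurious pairs with identity ~ U(20, 50) are added, and every hit is
    emitted in both directions (symmetric per genome pair).
    """
    cfg = result.config
    # the hits substream: second spawn of the root seed (evolve uses the first)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    truth = result.truth
    k = cfg.similarity_decay
    ident = 100.0 * np.exp(-k * truth["divergence_time"].to_numpy(float))
    if cfg.identity_noise_sd > 0:
        ident = ident + rng.normal(0.0, cfg.identity_noise_sd, len(ident))
    ident = np.clip(ident, 0.01, 100.0)
    frames = [
        pd.DataFrame(
            {
                "query": truth["gene_a"],
                "subject": truth["gene_b"],
                "identity": ident,
            }
        ),
        pd.DataFrame(
            {
                "query": truth["gene_b"],
                "subject": truth["gene_a"],
                "identity": ident,
            }
        ),
    ]
    n_spur = int(round(cfg.spurious_fraction * len(truth)))
    if n_spur > 0:
        all_genes = np.array(
            [g.gene_id for ann in result.annotations.values() for g in ann]
        )
        true_pairs = set(
            map(tuple, truth[["gene_a", "gene_b"]].itertuples(index=False))
        )
        qs: list[str] = []
        ss: list[str] = []
        while len(qs) < n_spur:
            need = n_spur - len(qs)
            ia = rng.integers(0, len(all_genes), 2 * need)
            ib = rng.integers(0, len(all_genes), 2 * need)
            for a, b in zip(all_genes[ia], all_genes[ib]):
                if a == b:
                    continue
                key = (a, b) if a <= b else (b, a)
                if key in true_pairs:
                    continue
                qs.append(a)
                ss.append(b)
                if len(qs) == n_spur:
                    break
        spur = pd.DataFrame(
            {
                "query": qs,
                "subject": ss,
                "identity": rng.uniform(20.0, 50.0, n_spur),
            }
        )
        frames.append(spur)
        frames.append(
            spur.rename(columns={"query": "subject", "subject": "query"})
        )
    hits = pd.concat(frames, ignore_index=True)
    hits["evalue"] = np.power(10.0, 4.0 - 0.3 * hits["identity"])
    hits["bitscore"] = 2.0 * hits["identity"]
    hits = hits.sort_values(["query", "subject"], kind="mergesort").reset_index(
        drop=True
    )
    return hits[["query", "subject", "identity", "evalue", "bitscore"]]


# ---------------------------------------------------------------------------
# rearrangement primitives (shared by simulator and public API)
# ---------------------------------------------------------------------------

def apply_inversion(state: dict[str, list], rng: np.random.Generator) -> None:
    chroms = [c for c in sorted(state) if len(state[c]) >= 2]
    if not chroms:
        return
    weights = np.array([len(state[c]) for c in chroms], dtype=float)
    chrom = chroms[rng.choice(len(chroms), p=weights / weights.sum())]
    n = len(state[chrom])
    i, j = sorted(rng.choice(n + 1, 2, replace=False))
    state[chrom][i:j] = state[chrom][i:j][::-1]


def apply_translocation(state: dict[str, list], rng: np.random.Generator) -> None:
    chroms = sorted(state)
    if len(chroms) < 2:
        return
    nonempty = [c for c in chroms if state[c]]
    if not nonempty:
        return
    src = nonempty[int(rng.integers(len(nonempty)))]
    n = len(state[src])
    length = int(min(n, 1 + rng.geometric(0.2)))
    start = int(rng.integers(n - length + 1))
    segment = state[src][start : start + length]
    del state[src][start : start + length]
    others = [c for c in chroms if c != src]
    dst = others[int(rng.integers(len(others)))]
    pos = int(rng.integers(len(state[dst]) + 1))
    state[dst][pos:pos] = segment


def apply_fission(
    state: dict[str, list],
    rng: np.random.Generator,
    chromosome: str | None = None,
) -> None:
    """Split one chromosome into two; skipped (with a log entry) when the
    target has fewer than two genes."""
    if chromosome is None:
        chromosome = max(sorted(state), key=lambda c: len(state[c]))
    if len(state.get(chromosome, [])) < 2:
        log.warning("fission skipped: chromosome %r has <2 genes", chromosome)
        return
    genes = state[chromosome]
    cut = int(rng.integers(1, len(genes)))
    new_name = f"{chromosome}.fis"
    while new_name in state:
        new_name += "x"
    state[chromosome] = genes[:cut]
    state[new_name] = genes[cut:]


def apply_rearrangements(
    ann: GenomeAnnotation,
    n_inversions: int = 0,
    n_translocations: int = 0,
    fissions: int | list[str] = 0,
    rng: np.random.Generator | int | None = None,
) -> GenomeAnnotation:
    """Apply rearrangements to an annotation and re-rank the result.

    ``fissions`` is either a count (largest chromosome split each time) or a
    list of chromosome names to split.  Gene content is conserved exactly;
    base-pair coordinates are regenerated from the new gene order.
    """
    if ann.n_genes == 0:
        raise ValueError(f"genome {ann.genome_id!r} is empty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    state: dict[str, list[Gene]] = {
        chrom: list(genes) for chrom, genes in ann.chromosomes.items()
    }
    for _ in range(n_inversions):
        apply_inversion(state, rng)
    for _ in range(n_translocations):
        apply_translocation(state, rng)
    if isinstance(fissions, int):
        for _ in range(fissions):
            apply_fission(state, rng)
    else:
        for chrom in fissions:
            apply_fission(state, rng, chrom)
    genes: list[Gene] = []
    for chrom in sorted(state):
        for pos, g in enumerate(state[chrom], start=1):
            start = (pos - 1) * 1000 + 1
            genes.append(
                Gene(g.gene_id, ann.genome_id, chrom, 0, start, start + 599,
                     g.strand)
            )
    return GenomeAnnotation.from_genes(ann.genome_id, genes)
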