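"""Constrained stochastic growth of star-hyperbranched polymer topologies.

Growth expands a tree outward from a multifunctional core.  Hydrophobic
epoxide units are laid down first as linear blocks, one per arm, mirroring
the two-stage synthesis (alkyl-epoxide star first, glycidol shell second).
The glycidol shell then grows by repeatedly picking a random open attachment
site and a random remaining monomer.  Terminal (capping) monomers are only
eligible while the ramification ratio and the placed non-terminal fraction
both meet their thresholds; a growth attempt that strands unplaced monomers
is discarded and re-sampled from a deterministic seed sequence, so only
topologies that consume the full monomer budget are ever returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .errors import GrowthExhausted, InfeasibleConstraints, UnresolvedAttachment
from .monomers import GrowthConstraints, MonomerSpec

__all__ = [
    "PolymerTopology",
    "PolymerEnsemble",
    "grow_polymer",
    "generate_ensemble",
    "degree_of_branching",
    "topology_to_smiles",
]


@dataclass
class GrowthStep:
    """One stochastic choice, recorded for constraint-replay audits."""

    node_id: int
    monomer: str
    ramification_ratio: float
    nonterminal_fraction: float


@dataclass
class PolymerTopology:
    """A rooted tree of monomer instances.

    ``nodes`` maps node id to monomer name; ``edges`` are
    ``(parent_id, site_index, child_id)`` with ``site_index`` the open
    attachment site of the parent that was consumed.  Node 0 is the core.
    """

    nodes: dict[int, str]
    edges: list[tuple[int, int, int]]
    root: int
    pool: dict[str, MonomerSpec]
    trace: list[GrowthStep] = field(default_factory=list)

    # -- derived structure ------------------------------------------------
    def children(self, node_id: int) -> list[int]:
        return [c for p, _, c in self.edges if p == node_id]

    def parent(self, node_id: int) -> int | None:
        for p, _, c in self.edges:
            if c == node_id:
                return p
        return None

    def spec(self, node_id: int) -> MonomerSpec:
        return self.pool[self.nodes[node_id]]

    @property
    def dp_n(self) -> int:
        """Degree of polymerization: monomer count excluding the core."""
        return len(self.nodes) - 1

    @property
    def mn_formula(self) -> float:
        """Formula molecular weight: sum of residue masses, g/mol."""
        return sum(self.pool[name].mass for name in self.nodes.values())

    @property
    def type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for name in self.nodes.values():
            counts[name] = counts.get(name, 0) + 1
        counts.pop(self.nodes[self.root], None)
        return counts

    @property
    def db(self) -> float:
        return degree_of_branching(self)

    def validate(self) -> None:
        """Check tree structure and valence safety; raise on violation."""
        n_children: dict[int, int] = {i: 0 for i in self.nodes}
        seen_child: set[int] = set()
        for p, site, c in self.edges:
            if c in seen_child:
                raise ValueError(f"node {c} has two parents")
            seen_child.add(c)
            n_children[p] += 1
            if site < 0 or site >= self.spec(p).n_attachment_points:
                raise ValueError(f"edge uses invalid site {site} on node {p}")
        if self.root in seen_child:
            raise ValueError("root must not have a parent")
        if len(seen_child) != len(self.nodes) - 1:
            raise ValueError("graph is not a tree rooted at the core")
        for i, k in n_children.items():
            if k > self.spec(i).n_attachment_points:
                raise ValueError(f"node {i} exceeds its attachment-site count")

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "root": self.root,
                "nodes": {str(i): name for i, name in self.nodes.items()},
                "edges": [list(e) for e in self.edges],
            }
        )

    @classmethod
    def from_json(cls, text: str, pool: list[MonomerSpec]) -> "PolymerTopology":
        data = json.loads(text)
        return cls(
            nodes={int(i): name for i, name in data["nodes"].items()},
            edges=[tuple(e) for e in data["edges"]],
            root=data["root"],
            pool={m.name: m for m in pool},
        )

    def signature(self) -> tuple:
        """Order-independent canonical form (attachment sites are equivalent)."""

        def rec(node_id: int) -> tuple:
            subs = sorted(rec(c) for c in self.children(node_id))
            return (self.nodes[node_id], tuple(subs))

        return rec(self.root)


@dataclass
class PolymerEnsemble:
    """Topology variants grown under one set of constraints ("HbPMM" set)."""

    variants: list[PolymerTopology]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("ensemble needs at least one variant")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)


def _check_feasible(pool: dict[str, MonomerSpec], constraints: GrowthConstraints) -> None:
    for name in constraints.quantity_per_monomer:
        if name not in pool:
            raise InfeasibleConstraints(f"quantity given for unknown monomer {name!r}")
    open_valences = constraints.n_arms
    for name, qty in constraints.quantity_per_monomer.items():
        open_valences += qty * pool[name].n_attachment_points
    if open_valences < constraints.total_monomers:
        raise InfeasibleConstraints(
            f"total open valences ({open_valences}) cannot host "
            f"{constraints.total_monomers} monomers"
        )


def _ramification_ratio(placed: dict[str, int], pool: dict[str, MonomerSpec]) -> float:
    d = sum(n for name, n in placed.items() if pool[name].role == "glycidol_dendritic")
    lin = sum(n for name, n in placed.items() if pool[name].role == "glycidol_linear")
    if d + lin == 0:
        return 1.0
    return d / (d + lin)


def _nonterminal_fraction(placed: dict[str, int], pool: dict[str, MonomerSpec]) -> float:
    total = sum(placed.values())
    if total == 0:
        return 1.0
    nonterm = sum(n for name, n in placed.items() if not pool[name].is_terminal)
    return nonterm / total


def _attempt_growth(
    pool: dict[str, MonomerSpec],
    constraints: GrowthConstraints,
    rng: np.random.Generator,
) -> PolymerTopology | None:
    core = next((m for m in pool.values() if m.role == "core"), None)
    if core is None:
        raise InfeasibleConstraints("pool has no core monomer")

    topo = PolymerTopology(nodes={0: core.name}, edges=[], root=0, pool=pool)
    next_id = 1
    # open sites as (node_id, site_index); core exposes n_arms sites
    n_core_sites = min(core.n_attachment_points, constraints.n_arms)
    open_sites: list[tuple[int, int]] = [(0, s) for s in range(n_core_sites)]
    remaining = dict(constraints.quantity_per_monomer)
    placed: dict[str, int] = {name: 0 for name in remaining}

    def place(site: tuple[int, int], name: str) -> int:
        nonlocal next_id
        node_id = next_id
        next_id += 1
        topo.nodes[node_id] = name
        topo.edges.append((site[0], site[1], node_id))
        open_sites.remove(site)
        spec = pool[name]
        for s in range(spec.n_attachment_points):
            open_sites.append((node_id, s))
        remaining[name] -= 1
        placed[name] += 1
        topo.trace.append(
            GrowthStep(
                node_id,
                name,
                _ramification_ratio(placed, pool),
                _nonterminal_fraction(placed, pool),
            )
        )
        return node_id

    # stage 1: hydrophobic blocks, one linear run per arm (block architecture)
    hydro = [name for name in remaining if pool[name].role == "hydrophobic_linear"]
    for name in hydro:
        qty = remaining[name]
        per_arm = [qty // n_core_sites] * n_core_sites
        for i in range(qty % n_core_sites):
            per_arm[i] += 1
        for arm in range(n_core_sites):
            site = (0, arm)
            for _ in range(per_arm[arm]):
                if site not in open_sites:
                    return None
                node_id = place(site, name)
                site = (node_id, 0)

    # stage 2: stochastic shell growth
    while any(q > 0 for q in remaining.values()):
        if not open_sites:
            return None
        site = open_sites[rng.integers(len(open_sites))]
        ram = _ramification_ratio(placed, pool)
        nonterm = _nonterminal_fraction(placed, pool)
        allow_terminal = (
            ram >= constraints.ramification_threshold
            and nonterm >= constraints.nonterminal_threshold
        )
        candidates = [
            name
            for name, qty in remaining.items()
            if qty > 0 and (allow_terminal or not pool[name].is_terminal)
        ]
        if not candidates:
            return None
        # weight by remaining instance counts: uniform over monomer instances
        weights = np.array([remaining[name] for name in candidates], dtype=float)
        name = candidates[rng.choice(len(candidates), p=weights / weights.sum())]
        place(site, name)

    topo.validate()
    return topo


def grow_polymer(
    pool: list[MonomerSpec],
    constraints: GrowthConstraints,
    max_restarts: int = 1000,
) -> PolymerTopology:
    """Grow one topology that consumes exactly the configured monomer budget.

    Dead ends (no open site or no eligible monomer while monomers remain)
    trigger a restart with the next seed in a deterministic sequence; after
    ``max_restarts`` failed attempts :class:`GrowthExhausted` is raised.
    """
    pool_map = {m.name: m for m in pool}
    _check_feasible(pool_map, constraints)
    for attempt in range(max_restarts):
        rng = np.random.default_rng([constraints.seed, attempt])
        topo = _attempt_growth(pool_map, constraints, rng)
        if topo is not None:
            return topo
    raise GrowthExhausted(
        f"no full-consumption topology found in {max_restarts} attempts"
    )


def generate_ensemble(
    pool: list[MonomerSpec],
    constraints: GrowthConstraints,
    n_variants: int,
    label: str = "",
) -> PolymerEnsemble:
    """Grow ``n_variants`` topologies from per-variant child seeds.

    Child seed for variant ``i`` is ``master_seed + i``, so the ensemble is
    fully determined by ``(seed, n_variants)``.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    import dataclasses

    variants = []
    for i in range(n_variants):
        c = dataclasses.replace(constraints, seed=constraints.seed + i)
        variants.append(grow_polymer(pool, c))
    return PolymerEnsemble(variants=variants, label=label)


def degree_of_branching(topology: PolymerTopology) -> float:
    """Frey/Hoelter degree of branching DB = 2D/(2D + L) over glycidol units.

    D counts glycidol units with both substitution sites occupied, L those
    with exactly one.  Returns 0 when the polymer carries no glycidol units.
    """
    d = lin = 0
    n_children: dict[int, int] = {i: 0 for i in topology.nodes}
    for p, _, _c in topology.edges:
        n_children[p] += 1
    has_glycidol = False
    for node_id, name in topology.nodes.items():
        if topology.pool[name].is_glycidol:
            has_glycidol = True
            k = n_children[node_id]
            if k >= 2:
                d += 1
            elif k == 1:
                lin += 1
    if not has_glycidol or (d == 0 and lin == 0):
        return 0.0
    return 2 * d / (2 * d + lin)


def topology_to_smiles(topology: PolymerTopology) -> str:
    """Render a topology to a canonical SMILES string.

    Fragments are joined dummy-to-dummy: the child's inbound carbon bonds to
    the oxygen carrying the parent's consumed site.  Open sites left unused
    after growth are capped as hydroxyls (the dummy is removed and the oxygen
    keeps an implicit hydrogen).
    """
    combined = Chem.RWMol()
    # per node: (in_dummy_combined_idx | None, [out_dummy_combined_idx...])
    anchor: dict[int, tuple[int | None, list[int]]] = {}
    for node_id, name in topology.nodes.items():
        spec = topology.pool[name]
        frag = Chem.MolFromSmiles(spec.template)
        if frag is None:
            raise UnresolvedAttachment(f"template for {name} does not parse")
        offset = combined.GetNumAtoms()
        combined.InsertMol(frag)
        dummies = [
            a.GetIdx() + offset for a in frag.GetAtoms() if a.GetAtomicNum() == 0
        ]
        if spec.role == "core":
            anchor[node_id] = (None, dummies)
        else:
            anchor[node_id] = (dummies[0], dummies[1:])

    def heavy_neighbor(idx: int) -> int:
        nbrs = combined.GetAtomWithIdx(idx).GetNeighbors()
        if len(nbrs) != 1:
            raise UnresolvedAttachment("attachment dummy must have one neighbor")
        return nbrs[0].GetIdx()

    for parent_id, site, child_id in topology.edges:
        _, parent_out = anchor[parent_id]
        child_in, _ = anchor[child_id]
        if site >= len(parent_out) or child_in is None:
            raise UnresolvedAttachment(
                f"edge ({parent_id}->{child_id}) references a missing site"
            )
        combined.AddBond(
            heavy_neighbor(parent_out[site]),
            heavy_neighbor(child_in),
            Chem.BondType.SINGLE,
        )

    # drop every dummy (used ones are now bypassed; unused oxygens become OH)
    for idx in sorted(
        (a.GetIdx() for a in combined.GetAtoms() if a.GetAtomicNum() == 0),
        reverse=True,
    ):
        combined.RemoveAtom(idx)

    mol = combined.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)
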