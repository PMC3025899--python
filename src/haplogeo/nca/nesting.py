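"""Hierarchical nesting of a haplotype network into 1-step, 2-step, … clades.

The nesting rules start at the tips of the cladogram and move one mutational
connection inward, uniting each tip with its interior neighbor into a clade;
the united units are pruned and the procedure repeats on the interior
residue until all units are nested. The same rules then apply one level up,
with the freshly formed clades as units, until a level would contain only a
single category — that single category is the total cladogram.

Two conventions not fixed by the linking rules themselves:

* Reticulations (loops) are broken, for nesting only, at the edge joining
  the two lowest-frequency haplotypes — the standard frequency criterion
  for resolving ambiguity, since rarer haplotypes are less likely to be the
  true mutational neighbors.
* A unit stranded after pruning (its neighbors all consumed) attaches to
  the adjacent already-formed clade with the fewest members; ties prefer a
  clade whose connecting unit was that clade's uniting interior, then the
  lexicographically smallest clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from ..haplonet import HaplotypeNetwork


@dataclass
class Clade:
    clade_id: str
    level: int
    members: list[str]  # unit ids one level down (haplotype ids at level 1)
    status: str | None = None  # "tip" | "interior" | None (no siblings)
    parent: str | None = None


@dataclass
class NestingDesign:
    """All clades of the nesting hierarchy, including the total cladogram."""

    clades: list[Clade]
    broken_edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {c.clade_id: c for c in self.clades}

    def clade(self, clade_id: str) -> Clade:
        return self._by_id[clade_id]

    def levels(self) -> list[int]:
        return sorted({c.level for c in self.clades})

    def at_level(self, level: int) -> list[Clade]:
        return [c for c in self.clades if c.level == level]

    @property
    def total(self) -> Clade:
        return self._by_id["total"]

    def haplotypes_of(self, clade_id: str) -> list[str]:
        """All haplotype ids contained (recursively) in a clade."""
        clade = self._by_id.get(clade_id)
        if clade is None:
            return [clade_id]  # a haplotype id is its own leaf unit
        out: list[str] = []
        for m in clade.members:
            out.extend(self.haplotypes_of(m))
        return out

    def nesting_parents(self) -> list[Clade]:
        """Clades that nest ≥ 1 unit: every clade (all contain members)."""
        return list(self.clades)


def _node_frequency(nw: HaplotypeNetwork, node: str) -> int:
    counts = nw.graph.nodes[node].get("counts")
    return sum(counts.values()) if counts else 1


def break_loops(nw: HaplotypeNetwork) -> tuple[nx.Graph, list[tuple[str, str]]]:
    """Return an acyclic copy of the network for nesting purposes.

    Cycles are broken one at a time by removing, from some remaining cycle,
    the edge joining the two lowest-frequency haplotypes (key: sorted pair
    of endpoint frequencies, then lexicographic edge), until no cycles
    remain. Removed edges are recorded.
    """
    g = nx.Graph()
    g.add_nodes_from(nw.graph.nodes(data=True))
    g.add_edges_from(nw.graph.edges(data=True))
    removed: list[tuple[str, str]] = []
    while True:
        cycles = nx.cycle_basis(g)
        if not cycles:
            break
        cycle = cycles[0]
        edges = [
            tuple(sorted((cycle[i], cycle[(i + 1) % len(cycle)])))
            for i in range(len(cycle))
        ]

        def key(e):
            fu, fv = _node_frequency(nw, e[0]), _node_frequency(nw, e[1])
            return (min(fu, fv), max(fu, fv), e)

        drop = min(edges, key=key)
        g.remove_edge(*drop)
        removed.append(drop)
    return g, removed


def _nest_one_level(graph: nx.Graph) -> list[list[str]]:
    """Partition the units of an acyclic graph into clades at one level."""
    remaining = set(graph.nodes)
    clades: list[list[str]] = []
    centers: list[str | None] = []  # uniting interior unit per clade
    unit_to_clade: dict[str, int] = {}

    def attach_stranded(u: str) -> None:
        """Attach a stranded unit to the best adjacent formed clade."""
        adjacent = sorted(
            {unit_to_clade[v] for v in graph.neighbors(u) if v in unit_to_clade}
        )
        if not adjacent:
            clades.append([u])
            centers.append(None)
            unit_to_clade[u] = len(clades) - 1
            return

        def key(ci: int) -> tuple:
            size = len(clades[ci])
            via_center = any(
                v in unit_to_clade
                and unit_to_clade[v] == ci
                and centers[ci] == v
                for v in graph.neighbors(u)
            )
            return (size, 0 if via_center else 1, sorted(clades[ci]))

        best = min(adjacent, key=key)
        clades[best].append(u)
        unit_to_clade[u] = best

    while remaining:
        deg = {
            u: sum(1 for v in graph.neighbors(u) if v in remaining)
            for u in remaining
        }
        isolated = sorted(u for u in remaining if deg[u] == 0)
        if isolated:
            for u in isolated:
                attach_stranded(u)
                remaining.discard(u)
            continue
        tips = sorted(u for u in remaining if deg[u] == 1)
        assigned: set[str] = set()
        for t in tips:
            if t in assigned:
                continue
            nb = next(v for v in graph.neighbors(t) if v in remaining)
            if nb in tips:
                # two-unit component: both tips unite with no clear interior
                group = sorted((t, nb))
                clades.append(group)
                centers.append(None)
                idx = len(clades) - 1
                for u in group:
                    unit_to_clade[u] = idx
                    assigned.add(u)
            else:
                group = [nb] + sorted(
                    u
                    for u in tips
                    if u not in assigned
                    and any(
                        v == nb for v in graph.neighbors(u) if v in remaining
                    )
                )
                clades.append(sorted(group))
                centers.append(nb)
                idx = len(clades) - 1
                for u in group:
                    unit_to_clade[u] = idx
                    assigned.add(u)
        remaining -= assigned
    return [sorted(c) for c in clades]


def _unit_graph(
    network: nx.Graph, unit_members: dict[str, list[str]]
) -> nx.Graph:
    """Graph on units; units adjacent when any network edge crosses them."""
    hap_to_unit: dict[str, str] = {}
    for uid, haps in unit_members.items():
        for h in haps:
            hap_to_unit[h] = uid
    g = nx.Graph()
    g.add_nodes_from(unit_members)
    for u, v in network.edges:
        cu, cv = hap_to_unit[u], hap_to_unit[v]
        if cu != cv:
            g.add_edge(cu, cv)
    return g


def build_nesting(nw: HaplotypeNetwork) -> NestingDesign:
    """Build the full nesting design from a haplotype network.

    Loops are first broken for nesting purposes (recorded on the design);
    tip/interior status is then assigned on the *full* network, including
    alternative edges, so loop members count all their connections. The
    hierarchy always contains the 1-step level; higher levels are added
    until a level would hold a single category, which becomes the clade
    ``total``.
    """
    tree, removed = break_loops(nw)
    haplotypes = sorted(nw.graph.nodes)
    clades: list[Clade] = []
    unit_members: dict[str, list[str]] = {h: [h] for h in haplotypes}

    level_graph = tree
    level = 1
    while True:
        groups = _nest_one_level(level_graph)
        if level > 1 and len(groups) == 1:
            # the next level would be a single category: the total cladogram
            total = Clade(clade_id="total", level=level, members=groups[0])
            clades.append(total)
            for c in clades:
                if c.clade_id in groups[0]:
                    c.parent = "total"
            break
        ids = [f"{level}-{i + 1}" for i in range(len(groups))]
        new_members = {
            cid: sorted(h for m in grp for h in _resolve(m, unit_members))
            for cid, grp in zip(ids, groups)
        }
        child_parent = {m: cid for cid, grp in zip(ids, groups) for m in grp}
        for c in clades:
            if c.clade_id in child_parent:
                c.parent = child_parent[c.clade_id]
        for cid, grp in zip(ids, groups):
            clades.append(Clade(clade_id=cid, level=level, members=sorted(grp)))
        unit_members.update(new_members)
        if len(groups) == 1:
            # a single 1-step clade: wrap it in the total cladogram
            clades.append(Clade(clade_id="total", level=2, members=list(ids)))
            clades[-2].parent = "total"
            break
        level_graph = _unit_graph(tree, new_members)
        level += 1
        if level > len(haplotypes) + 2:  # safety valve; cannot recurse deeper
            raise RuntimeError("nesting failed to converge")

    design = NestingDesign(clades=clades, broken_edges=removed)
    _assign_status(design, nw)
    return design


def _resolve(unit: str, unit_members: dict[str, list[str]]) -> list[str]:
    return unit_members.get(unit, [unit])


def classify_interior_tip(
    nw: HaplotypeNetwork, design: NestingDesign, unit_id: str
) -> str | None:
    """Tip/interior status of a unit within its nesting clade.

    A unit is a *tip* when exactly one mutational connection (edge of the
    full network, loops included) leaves it toward sibling units in the same
    nesting clade, and *interior* otherwise. When a nesting clade holds just
    two units — each with a single connection — the larger-frequency unit is
    deemed interior (older lineages are expected to be more frequent); an
    exact tie falls to the lexicographically first unit. A unit with no
    siblings has no status (``None``).
    """
    parent_id = _parent_of(design, unit_id)
    if parent_id is None:
        return None
    parent = design.clade(parent_id)
    siblings = [m for m in parent.members if m != unit_id]
    if not siblings:
        return None
    own = set(design.haplotypes_of(unit_id))
    sib_haps = {
        h for s in siblings for h in design.haplotypes_of(s)
    }
    connections = sum(
        1
        for u, v in nw.graph.edges
        if (u in own and v in sib_haps) or (v in own and u in sib_haps)
    )
    if len(parent.members) == 2:
        other = siblings[0]
        f_self = _unit_frequency(nw, design, unit_id)
        f_other = _unit_frequency(nw, design, other)
        if f_self != f_other:
            return "interior" if f_self > f_other else "tip"
        return "interior" if unit_id < other else "tip"
    return "tip" if connections == 1 else "interior"


def _unit_frequency(nw: HaplotypeNetwork, design: NestingDesign, unit_id: str) -> int:
    return sum(_node_frequency(nw, h) for h in design.haplotypes_of(unit_id))


def _parent_of(design: NestingDesign, unit_id: str) -> str | None:
    try:
        return design.clade(unit_id).parent
    except KeyError:
        # haplotype unit: parent is the 1-step clade containing it
        for c in design.at_level(1):
            if unit_id in c.members:
                return c.clade_id
        return None


def _assign_status(design: NestingDesign, nw: HaplotypeNetwork) -> None:
    for c in design.clades:
        if c.clade_id == "total":
            c.status = None
        else:
            c.status = classify_interior_tip(nw, design, c.clade_id)


def read_clade_memberships(path) -> NestingDesign:
    """Read a fixed nesting design from a TSV (clade, level, members).

    ``members`` is a comma-separated list of haplotype ids (level 1) or
    child clade ids (higher levels); a row with clade id ``total`` holds
    the top-level clades. Statuses are left unassigned.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    clades = [
        Clade(
            clade_id=str(r["clade"]),
            level=int(r["level"]),
            members=str(r["members"]).split(","),
        )
        for _, r in df.iterrows()
    ]
    design = NestingDesign(clades=clades)
    for c in clades:
        for m in c.members:
            try:
                design.clade(m).parent = c.clade_id
            except KeyError:
                pass  # haplotype leaf unit
    return design


def unit_status(
    nw: HaplotypeNetwork, design: NestingDesign, unit_id: str
) -> str | None:
    """Status for any unit id — clade or bare haplotype."""
    try:
        return design.clade(unit_id).status
    except KeyError:
        return classify_interior_tip(nw, design, unit_id)
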