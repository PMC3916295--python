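"""The discordant graph and prototype-based SV identification.

Breakpoints are vertices; each discordant fragment contributes a typed,
directed edge between the two coordinates it connects, weighted by the
number of supporting read pairs.  Because the orientation in which a
fragment is sequenced is arbitrary, edges are reduced to canonical
representatives under the orientation-swap equivalences

    a(u,v) == a(v,u),    d(u,v) == d(v,u),    b(u,v) == c(v,u),

i.e. the symmetric types a/d/e keep lexicographically ordered endpoints and
every c-edge is rewritten as the b-edge read from its left-approached
endpoint.  Connected components of the resulting multigraph are candidate
SVs and are identified by edge-type-aware isomorphism to a catalog of 16
prototype graphs: small insertion, deletion, tandem duplication, inversion,
and insertional duplication / translocation in each combination of
{intrachromosomal downstream, intrachromosomal upstream, interchromosomal}
x {non-inverted, inverted}.

Donor-adjacency edges (type e) join the two boundaries of a duplicated
donor.  They are derived during graph construction: within a component, any
same-chromosome vertex pair that is not already joined by a sequence-level
junction edge and lies within the maximal donor span receives an e-edge.
A translocation differs from an insertional duplication exactly by the donor
excision junction b(dstart,dend); since that edge joins the donor
boundaries, translocation components carry no e-edge and the two signatures
stay distinct.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Callable, Iterable, Optional

from .breakpointing import EvidenceEdge, FragmentEvidence
from .config import PipelineConfig, DEFAULT_CONFIG

Coord = tuple[str, int]


@dataclass(frozen=True, order=True)
class CanonicalEdge:
    type: str  # a | b | d | e  (c is always rewritten as b)
    u: Coord
    v: Coord


@dataclass
class DiscordantEdge:
    type: str
    u: Coord
    v: Coord
    weight: int = 1
    sv_seqs: Counter = field(default_factory=Counter)
    derived: bool = False  # True for e-edges added at graph construction

    @property
    def key(self) -> CanonicalEdge:
        return CanonicalEdge(self.type, self.u, self.v)


def canonicalize_edge(edge: EvidenceEdge | tuple[str, Coord, Coord]) -> CanonicalEdge:
    """Canonical representative of an edge under orientation equivalence."""
    if isinstance(edge, EvidenceEdge):
        etype, u, v = edge.type, edge.u.coord, edge.v.coord
    else:
        etype, u, v = edge
    if etype == "c":
        etype, u, v = "b", v, u
    if etype in ("a", "d", "e") and v < u:
        u, v = v, u
    return CanonicalEdge(etype, u, v)


@dataclass
class Component:
    vertices: tuple[Coord, ...]
    edges: list[DiscordantEdge]

    @property
    def weight(self) -> int:
        """Minimum supporting read pairs over the sequence-level edges."""
        real = [e.weight for e in self.edges if not e.derived]
        return min(real) if real else 0


@dataclass
class DiscordantGraph:
    edges: dict[CanonicalEdge, DiscordantEdge] = field(default_factory=dict)
    components: list[Component] = field(default_factory=list)

    @property
    def vertices(self) -> set[Coord]:
        out = set()
        for e in self.edges.values():
            out.add(e.u)
            out.add(e.v)
        return out


def _vertices_of(edges: Iterable[EvidenceEdge]) -> tuple[Coord, ...]:
    seen = []
    for e in edges:
        for c in (e.u.coord, e.v.coord):
            if c not in seen:
                seen.append(c)
    return tuple(sorted(seen))


def select_representative(collection: list) -> object:
    """Pick one graph from a collection of equivalent graphs.

    Higher order (more distinct breakpoints) wins; among ties the graph whose
    sorted breakpoint tuple is the lower median of the tied candidates is
    chosen, so equivalent placements inside repeats resolve to the central
    coordinates.
    """
    if not collection:
        raise ValueError("empty collection")
    keyed = [( _vertices_of(g), g) for g in collection]
    top = max(len(k) for k, _ in keyed)
    tied = sorted((k for k, _ in keyed if len(k) == top))
    target = tied[(len(tied) - 1) // 2]
    for k, g in keyed:
        if k == target:
            return g
    raise AssertionError("unreachable")


def build_discordant_graph(
    evidence: Iterable[FragmentEvidence],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> DiscordantGraph:
    """Assemble the discordant graph from per-fragment evidence.

    Each fragment may come with several equivalent breakpoint placements
    (co-optimal alignments).  Placements are first scored by how many other
    fragments support their breakpoints, so that independent fragments of the
    same event settle on identical coordinates and assemble the complete
    (highest-order) component; remaining ties resolve to the central
    placement.  The chosen placements are then merged into weighted canonical
    edges and donor-adjacency e-edges are derived per component.
    """
    evidence = list(evidence)
    chosen = _select_placements(evidence)
    graph = DiscordantGraph()
    for ev, placement in zip(evidence, chosen):
        for edge in placement:
            key = canonicalize_edge(edge)
            rec = graph.edges.get(key)
            if rec is None:
                rec = DiscordantEdge(key.type, key.u, key.v, weight=0)
                graph.edges[key] = rec
            rec.weight += 1
            if edge.sv_seq:
                rec.sv_seqs[edge.sv_seq] += 1

    _assign_components(graph, config)
    return graph


def _select_placements(
    evidence: list[FragmentEvidence], max_assignments: int = 4096
) -> list[tuple]:
    """Joint placement selection across fragments.

    Fragments carrying the same breakpoint information (identical canonical
    alternative sets -- e.g. all read pairs spanning one junction) form a
    group and always settle on the same placement.  Groups whose candidate
    breakpoints overlap form a cluster (the evidence of one SV); within a
    cluster one alternative is chosen per group so that the number of
    distinct breakpoints is minimal, i.e. independent junctions of the same
    event merge on shared coordinates and the complete, highest-order
    component assembles.  The true breakpoints are co-optimal for every
    fragment, so a fully merged assignment always exists; among equivalent
    optima the centrally placed one (lower-median breakpoint tuple) is
    reported.  Oversized clusters fall back to the per-group central
    placement.
    """
    def alt_key(alt) -> tuple:
        return tuple(
            sorted((canonicalize_edge(e), e.sv_seq) for e in alt)
        )

    groups: dict[tuple, dict] = {}
    member_group: list[tuple] = []
    for ev in evidence:
        gkey = tuple(sorted(alt_key(alt) for alt in ev.alternatives))
        rec = groups.get(gkey)
        if rec is None:
            rec = {"alts": sorted(ev.alternatives, key=_vertices_of), "choice": None}
            groups[gkey] = rec
        member_group.append(gkey)

    # cluster groups sharing any candidate breakpoint
    parent: dict[tuple, tuple] = {g: g for g in groups}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    vertex_owner: dict[Coord, tuple] = {}
    for gkey, rec in groups.items():
        for alt in rec["alts"]:
            for v in _vertices_of(alt):
                if v in vertex_owner:
                    ra, rb = find(vertex_owner[v]), find(gkey)
                    if ra != rb:
                        parent[ra] = rb
                else:
                    vertex_owner[v] = gkey

    clusters: dict[tuple, list[tuple]] = defaultdict(list)
    for gkey in groups:
        clusters[find(gkey)].append(gkey)

    for members in clusters.values():
        members.sort()
        n_assign = 1
        for gkey in members:
            n_assign *= len(groups[gkey]["alts"])
            if n_assign > max_assignments:
                break
        if n_assign > max_assignments:
            for gkey in members:
                groups[gkey]["choice"] = select_representative(groups[gkey]["alts"])
            continue
        candidates = []
        from itertools import product

        for combo in product(*(groups[g]["alts"] for g in members)):
            union = set()
            for alt in combo:
                union.update(_vertices_of(alt))
            candidates.append((len(union), tuple(sorted(union)), combo))
        best = min(c[0] for c in candidates)
        tied = sorted(c for c in candidates if c[0] == best)
        _, _, combo = tied[(len(tied) - 1) // 2]
        for gkey, alt in zip(members, combo):
            groups[gkey]["choice"] = alt

    return [groups[gkey]["choice"] for gkey in member_group]


def _assign_components(graph: DiscordantGraph, config: PipelineConfig) -> None:
    parent: dict[Coord, Coord] = {}

    def find(x: Coord) -> Coord:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: Coord, b: Coord) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for e in graph.edges.values():
        parent.setdefault(e.u, e.u)
        parent.setdefault(e.v, e.v)
        union(e.u, e.v)

    groups: dict[Coord, list[Coord]] = defaultdict(list)
    for v in parent:
        groups[find(v)].append(v)

    comp_edges: dict[Coord, list[DiscordantEdge]] = defaultdict(list)
    for e in graph.edges.values():
        comp_edges[find(e.u)].append(e)

    graph.components = []
    for root, verts in groups.items():
        edges = comp_edges[root]
        # derive donor-adjacency e-edges between unjoined same-chromosome pairs
        joined = {frozenset((e.u, e.v)) for e in edges}
        minw = min((e.weight for e in edges), default=1)
        derived = []
        for a, b in combinations(sorted(verts), 2):
            if a[0] != b[0] or abs(a[1] - b[1]) > config.e_max_span:
                continue
            if frozenset((a, b)) in joined:
                continue
            derived.append(DiscordantEdge("e", a, b, weight=minw, derived=True))
        all_edges = edges + derived
        for e in derived:
            graph.edges[e.key] = e
        graph.components.append(Component(tuple(sorted(verts)), all_edges))
    graph.components.sort(key=lambda c: c.vertices)


# ---------------------------------------------------------------------------
# prototypes


@dataclass(frozen=True)
class PrototypeEdge:
    type: str
    u: str  # role name
    v: str
    directed: bool


@dataclass
class PrototypeGraph:
    name: str
    roles: tuple[str, ...]
    edges: tuple[PrototypeEdge, ...]
    constraint: Callable[[dict[str, Coord]], bool]

    @property
    def arity(self) -> int:
        return len(self.roles)


def _b(u: str, v: str) -> PrototypeEdge:
    return PrototypeEdge("b", u, v, directed=True)


def _sym(t: str, u: str, v: str) -> PrototypeEdge:
    return PrototypeEdge(t, u, v, directed=False)


def _same_chrom(*coords: Coord) -> bool:
    return len({c[0] for c in coords}) == 1


def prototype_catalog() -> list[PrototypeGraph]:
    """The 16 SV prototype graphs in specificity order.

    Translocations precede insertional duplications (their signature is a
    superset in evidence richness), which precede the two-breakpoint types;
    the first matching prototype in this order identifies a component.
    Within the intrachromosomal non-inverted translocations the upstream
    variant precedes the downstream one: moving [s,e) upstream to p produces
    the identical sample sequence as moving [p,s) downstream past e, so both
    prototypes match the same 3-cycle and the upstream description is the
    canonical report.
    """
    protos: list[PrototypeGraph] = []

    def add(name, roles, edges, constraint):
        protos.append(PrototypeGraph(name, roles, tuple(edges), constraint))

    dup_roles = ("site", "dstart", "dend")

    def donor_ok(m):
        return _same_chrom(m["dstart"], m["dend"]) and m["dstart"][1] < m["dend"][1]

    def intra_up(m):
        return (
            donor_ok(m)
            and _same_chrom(m["site"], m["dstart"])
            and m["site"][1] <= m["dstart"][1]
        )

    def intra_down(m):
        return (
            donor_ok(m)
            and _same_chrom(m["site"], m["dstart"])
            and m["site"][1] >= m["dend"][1]
        )

    def inter(m):
        return donor_ok(m) and m["site"][0] != m["dstart"][0]

    fwd_junctions = [_b("site", "dstart"), _b("dend", "site")]
    inv_junctions = [_sym("a", "site", "dend"), _sym("d", "site", "dstart")]
    excision = _b("dstart", "dend")
    adjacency = _sym("e", "dstart", "dend")

    for place, cons in (("intra_up", intra_up), ("intra_down", intra_down), ("inter", inter)):
        add(f"translocation_{place}", dup_roles, fwd_junctions + [excision], cons)
        add(f"translocation_{place}_inverted", dup_roles, inv_junctions + [excision], cons)
    for place, cons in (("intra_up", intra_up), ("intra_down", intra_down), ("inter", inter)):
        add(f"insertional_duplication_{place}", dup_roles, fwd_junctions + [adjacency], cons)
        add(f"insertional_duplication_{place}_inverted", dup_roles, inv_junctions + [adjacency], cons)

    add(
        "inversion",
        ("start", "end"),
        [_sym("a", "start", "end"), _sym("d", "start", "end")],
        lambda m: _same_chrom(m["start"], m["end"]) and m["start"][1] < m["end"][1],
    )
    add(
        "tandem_duplication",
        ("start", "end"),
        [_b("end", "start")],
        lambda m: _same_chrom(m["start"], m["end"]) and m["start"][1] < m["end"][1],
    )
    add(
        "deletion",
        ("start", "end"),
        [_b("start", "end")],
        lambda m: _same_chrom(m["start"], m["end"]) and m["start"][1] < m["end"][1],
    )
    add("insertion", ("site",), [_b("site", "site")], lambda m: True)
    assert len(protos) == 16
    return protos


def _edge_key(etype: str, u: Coord, v: Coord) -> tuple:
    if etype == "b":
        return ("b", u, v)
    return (etype, *sorted((u, v)))


def match_component(component: Component, proto: PrototypeGraph) -> Optional[dict[str, Coord]]:
    """Edge-type-aware isomorphism of a component onto a prototype.

    Returns the role -> coordinate mapping of the first vertex bijection
    under which a typed edge exists between two component vertices iff the
    prototype connects their images with the same canonical type, and the
    prototype's coordinate constraints hold.  Vertex orderings are tried in
    sorted order, so the result is deterministic.
    """
    if len(component.vertices) != proto.arity:
        return None
    comp_keys = {_edge_key(e.type, e.u, e.v) for e in component.edges}
    if len(comp_keys) != len(proto.edges):
        return None
    for perm in permutations(sorted(component.vertices)):
        mapping = dict(zip(proto.roles, perm))
        proto_keys = {
            _edge_key(pe.type, mapping[pe.u], mapping[pe.v]) for pe in proto.edges
        }
        if proto_keys == comp_keys and proto.constraint(mapping):
            return mapping
    return None


# ---------------------------------------------------------------------------
# calls


@dataclass
class SVCall:
    type: str
    breakpoints: dict[str, Coord]
    sv_seq: str = ""
    weight: int = 1
    sample: str = ""
    zygosity: Optional[str] = None

    @property
    def chrom(self) -> str:
        return self.primary_coord[0]

    @property
    def primary_coord(self) -> Coord:
        role = "site" if "site" in self.breakpoints else "start"
        return self.breakpoints[role]

    def coords(self) -> list[Coord]:
        return sorted(self.breakpoints.values())


def call_svs(
    graph: DiscordantGraph,
    catalog: Optional[list[PrototypeGraph]] = None,
    mrw: int = 1,
    reference: Optional[dict[str, str]] = None,
    sample: str = "",
) -> tuple[list[SVCall], list[Component]]:
    """Match every component against the catalog and emit weighted calls.

    Components whose minimum sequence-level edge weight falls below ``mrw``
    are suppressed; components matching no prototype are returned as the
    residual (counted, not typed).
    """
    catalog = catalog if catalog is not None else prototype_catalog()
    calls: list[SVCall] = []
    residual: list[Component] = []
    for comp in graph.components:
        mapping = None
        proto = None
        for p in catalog:
            mapping = match_component(comp, p)
            if mapping is not None:
                proto = p
                break
        if mapping is None:
            residual.append(comp)
            continue
        if comp.weight < mrw:
            continue
        sv_seq = ""
        if proto.name == "insertion":
            seqs = Counter()
            for e in comp.edges:
                seqs.update(e.sv_seqs)
            if seqs:
                top = max(seqs.values())
                sv_seq = sorted(s for s, n in seqs.items() if n == top)[0]
        elif proto.name == "deletion" and reference is not None:
            chrom, s = mapping["start"]
            _, t = mapping["end"]
            sv_seq = reference[chrom][s:t]
        calls.append(
            SVCall(proto.name, dict(mapping), sv_seq, comp.weight, sample=sample)
        )
    calls.sort(key=lambda c: (c.primary_coord, c.type))
    return calls, residual


def to_networkx(graph: DiscordantGraph):
    """networkx MultiDiGraph view (for inspection and cross-checks)."""
    import networkx as nx

    g = nx.MultiDiGraph()
    for e in graph.edges.values():
        g.add_edge(e.u, e.v, type=e.type, weight=e.weight, derived=e.derived)
    return g


# ---------------------------------------------------------------------------
# export

_VCF_SVTYPE = {
    "insertion": "INS",
    "deletion": "DEL",
    "tandem_duplication": "DUP:TANDEM",
    "inversion": "INV",
}


def write_vcf(calls: list[SVCall], reference: dict[str, str], path: str,
              sample: str = "sample") -> None:
    """Symbolic-allele VCF 4.2 export; 3-breakpoint events become BND pairs."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=SEQ,Number=1,Type=String,Description="Inserted/deleted sequence">\n')
        fh.write('##INFO=<ID=WEIGHT,Number=1,Type=Integer,Description="Supporting read pairs">\n')
        fh.write('##INFO=<ID=EVENT,Number=1,Type=String,Description="Event id">\n')
        fh.write('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">\n')
        for chrom in sorted(reference):
            fh.write(f"##contig=<ID={chrom},length={len(reference[chrom])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        n = 0
        for call in calls:
            n += 1
            cid = f"sv{n}"
            if call.type in _VCF_SVTYPE:
                chrom, pos = call.primary_coord
                ref_base = reference[chrom][max(0, pos - 1)] if reference else "N"
                svtype = _VCF_SVTYPE[call.type]
                info = [f"SVTYPE={svtype}", f"WEIGHT={call.weight}"]
                if call.type == "insertion":
                    info.append(f"SVLEN={len(call.sv_seq)}")
                    if call.sv_seq:
                        info.append(f"SEQ={call.sv_seq}")
                    alt = f"{ref_base}{call.sv_seq}" if call.sv_seq else "<INS>"
                else:
                    end = call.breakpoints["end"][1]
                    info.append(f"END={end}")
                    length = end - call.breakpoints["start"][1]
                    info.append(f"SVLEN={-length if call.type == 'deletion' else length}")
                    if call.type == "deletion" and call.sv_seq:
                        info.append(f"SEQ={call.sv_seq}")
                    alt = f"<{svtype.split(':')[0]}>"
                fh.write(
                    f"{chrom}\t{pos}\t{cid}\t{ref_base}\t{alt}\t.\tPASS\t{';'.join(info)}\n"
                )
            else:
                # duplicative/translocated events: one breakend per breakpoint
                coords = sorted(call.breakpoints.items())
                for idx, (role, (chrom, pos)) in enumerate(coords):
                    mate = coords[(idx + 1) % len(coords)]
                    ref_base = reference[chrom][max(0, pos - 1)] if reference else "N"
                    info = (
                        f"SVTYPE=BND;EVENT={cid}:{call.type};WEIGHT={call.weight};"
                        f"MATEID={cid}_{(idx + 1) % len(coords)}"
                    )
                    alt = f"{ref_base}[{mate[1][0]}:{mate[1][1] + 1}["
                    fh.write(
                        f"{chrom}\t{pos}\t{cid}_{idx}\t{ref_base}\t{alt}\t.\tPASS\t{info}\n"
                    )


def write_calls_tsv(calls: list[SVCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("type\tbreakpoints\tsv_seq\tweight\tsample\tzygosity\n")
        for c in calls:
            bps = ";".join(f"{role}={chrom}:{pos}" for role, (chrom, pos) in sorted(c.breakpoints.items()))
            fh.write(f"{c.type}\t{bps}\t{c.sv_seq}\t{c.weight}\t{c.sample}\t{c.zygosity or ''}\n")


def write_edge_list(graph: DiscordantGraph, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("type\tchrom_u\tpos_u\tchrom_v\tpos_v\tweight\tderived\n")
        for e in sorted(graph.edges.values(), key=lambda e: (e.u, e.v, e.type)):
            fh.write(
                f"{e.type}\t{e.u[0]}\t{e.u[1]}\t{e.v[0]}\t{e.v[1]}\t{e.weight}\t{int(e.derived)}\n"
            )


def write_residual_json(residual: list[Component], path: str) -> None:
    data = [
        {
            "vertices": [list(v) for v in comp.vertices],
            "edges": [
                {"type": e.type, "u": list(e.u), "v": list(e.v), "weight": e.weight}
                for e in comp.edges
            ],
        }
        for comp in residual
    ]
    with open(path, "w") as fh:
        json.dump({"n_unmatched": len(data), "components": data}, fh, indent=1)
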