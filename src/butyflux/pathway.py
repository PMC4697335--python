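"""Atom-mapped pathway model: metabolites, reactions, branch topology.

The packaged configuration encodes the butyrogenic pathway of *Intestinimonas*
AF211: the 10-step lysine branch (lysine cleaved between C2 and C3, carbons
3-6 becoming butyrate), the acetyl-CoA condensation branch, the
fructoselysine entry reactions, and lactate overflow. Validation enforces
carbon conservation for every reaction's atom map and reachability of the
target product from each declared labelled substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import networkx as nx
import yaml

from .chem import Metabolite
from .errors import PathwayValidationError

SCHEMA_VERSION = 1

BRANCHES = ("lysine", "acetyl_coa", "fructoselysine_entry", "overflow")


def split_instance(ref: str) -> tuple[str, int]:
    """Split an atom-map metabolite reference ``"name"`` / ``"name/k"``."""
    if "/" in ref:
        base, _, inst = ref.rpartition("/")
        return base, int(inst)
    return ref, 1


@dataclass(frozen=True)
class AtomMappedReaction:
    """A stoichiometric reaction with a carbon-to-carbon atom map.

    ``atom_map`` entries are ``(substrate_ref, carbon, product_ref, carbon)``
    with 1-based carbon indices; refs may carry ``/k`` instance suffixes for
    species with stoichiometric coefficient > 1.
    """

    id: str
    substrates: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    atom_map: tuple[tuple[str, int, str, int], ...]
    enzyme_label: str = ""
    pathway_branch: str = "lysine"

    def __post_init__(self):
        if self.pathway_branch not in BRANCHES:
            raise PathwayValidationError(
                f"reaction {self.id!r}: unknown branch {self.pathway_branch!r}"
            )
        for name, coeff in self.substrates + self.products:
            if coeff <= 0:
                raise PathwayValidationError(
                    f"reaction {self.id!r}: non-positive coefficient for {name!r}"
                )

    def validate_carbon_map(self, metabolites: Mapping[str, Metabolite]) -> None:
        """Check that every substrate carbon maps to exactly one product
        carbon and vice versa (carbon conservation)."""
        expected_src = self._instance_carbons(self.substrates, metabolites)
        expected_dst = self._instance_carbons(self.products, metabolites)
        seen_src: set = set()
        seen_dst: set = set()
        for sm, si, pm, pi in self.atom_map:
            s_key = (*split_instance(sm), si)
            p_key = (*split_instance(pm), pi)
            if s_key not in expected_src:
                raise PathwayValidationError(
                    f"reaction {self.id!r}: atom map source {sm} C{si} does not exist"
                )
            if p_key not in expected_dst:
                raise PathwayValidationError(
                    f"reaction {self.id!r}: atom map target {pm} C{pi} does not exist"
                )
            if s_key in seen_src:
                raise PathwayValidationError(
                    f"reaction {self.id!r}: carbon {sm} C{si} mapped twice (duplication)"
                )
            if p_key in seen_dst:
                raise PathwayValidationError(
                    f"reaction {self.id!r}: carbon {pm} C{pi} produced twice (duplication)"
                )
            seen_src.add(s_key)
            seen_dst.add(p_key)
        missing_src = expected_src - seen_src
        if missing_src:
            m, k, i = sorted(missing_src)[0]
            raise PathwayValidationError(
                f"reaction {self.id!r}: substrate carbon {m}/{k} C{i} lost (not mapped)"
            )
        missing_dst = expected_dst - seen_dst
        if missing_dst:
            m, k, i = sorted(missing_dst)[0]
            raise PathwayValidationError(
                f"reaction {self.id!r}: product carbon {m}/{k} C{i} has no source"
            )

    @staticmethod
    def _instance_carbons(side, metabolites):
        carbons = set()
        for name, coeff in side:
            met = metabolites.get(name)
            if met is None:
                raise PathwayValidationError(f"unknown metabolite {name!r}")
            if met.n_carbons == 0:
                continue
            if coeff != int(coeff):
                raise PathwayValidationError(
                    f"fractional coefficient for carbon-bearing species {name!r}"
                )
            for k in range(1, int(coeff) + 1):
                for i in range(1, met.n_carbons + 1):
                    carbons.add((name, k, i))
        return carbons


@dataclass
class PathwayModel:
    """Validated collection of metabolites and atom-mapped reactions."""

    metabolites: dict[str, Metabolite]
    reactions: list[AtomMappedReaction]
    labelled_substrates: tuple[str, ...] = ("lysine",)
    target: str = "butyrate"
    branch_index: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.branch_index:
            self.branch_index = {b: [] for b in BRANCHES}
            for r in self.reactions:
                self.branch_index[r.pathway_branch].append(r.id)
        self.validate()

    def reaction(self, rxn_id: str) -> AtomMappedReaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def metabolite(self, name: str) -> Metabolite:
        return self.metabolites[name]

    def validate(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise PathwayValidationError("duplicate reaction ids")
        for r in self.reactions:
            for name, _ in r.substrates + r.products:
                if name not in self.metabolites:
                    raise PathwayValidationError(
                        f"reaction {r.id!r} references unknown metabolite {name!r}"
                    )
            r.validate_carbon_map(self.metabolites)
        g = self.carbon_graph()
        for sub in self.labelled_substrates:
            if sub not in self.metabolites:
                raise PathwayValidationError(f"labelled substrate {sub!r} not defined")
            if self.target not in nx.descendants(g, sub):
                raise PathwayValidationError(
                    f"target {self.target!r} unreachable from substrate {sub!r}"
                )

    def carbon_graph(self) -> "nx.DiGraph":
        """Directed metabolite graph with an edge wherever an atom map
        carries at least one carbon."""
        g = nx.DiGraph()
        g.add_nodes_from(self.metabolites)
        for r in self.reactions:
            for sm, _, pm, _ in r.atom_map:
                g.add_edge(split_instance(sm)[0], split_instance(pm)[0], reaction=r.id)
        return g


def load_pathway(path=None) -> PathwayModel:
    """Load and validate a pathway config; default is the packaged model."""
    if path is None:
        with resources.files("butyflux.data").joinpath("pathway.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    version = raw.get("schema_version")
    if version != SCHEMA_VERSION:
        raise PathwayValidationError(f"unsupported schema_version {version!r}")
    mets = {
        m["name"]: Metabolite.from_formula(m["name"], m["formula"])
        for m in raw["metabolites"]
    }
    reactions = []
    for r in raw["reactions"]:
        reactions.append(
            AtomMappedReaction(
                id=r["id"],
                substrates=tuple((s["metabolite"], float(s["coeff"])) for s in r["substrates"]),
                products=tuple((p["metabolite"], float(p["coeff"])) for p in r["products"]),
                atom_map=tuple((e[0], int(e[1]), e[2], int(e[3])) for e in r["atom_map"]),
                enzyme_label=r.get("enzyme", ""),
                pathway_branch=r["branch"],
            )
        )
    return PathwayModel(
        metabolites=mets,
        reactions=reactions,
        labelled_substrates=tuple(raw.get("labelled_substrates", ("lysine",))),
        target=raw.get("target", "butyrate"),
    )


def branch_carbon_fate(
    model: PathwayModel,
    branches: Sequence[str] | str,
    source: str,
) -> tuple[dict[str, dict[int, int]], set[str]]:
    """Trace where each carbon of ``source`` can end up within a set of
    branches, composing atom maps to a fixed point.

    Returns ``(fates, ambiguous)``: ``fates[metabolite][src_carbon] ->
    dst_carbon`` for metabolites where every reachable source carbon lands on
    a unique position; metabolites where some carbon can land on two
    different positions are listed in ``ambiguous`` and omitted from fates.
    Instance suffixes are collapsed: carbons live on metabolite pools.
    """
    if isinstance(branches, str):
        branches = (branches,)
    rxns = [r for r in model.reactions if r.pathway_branch in branches]
    n = model.metabolite(source).n_carbons
    fate: dict[int, set[tuple[str, int]]] = {c: {(source, c)} for c in range(1, n + 1)}
    changed = True
    while changed:
        changed = False
        for r in rxns:
            for sm, si, pm, pi in r.atom_map:
                s_base = split_instance(sm)[0]
                p_base = split_instance(pm)[0]
                for c in fate:
                    if (s_base, si) in fate[c] and (p_base, pi) not in fate[c]:
                        fate[c].add((p_base, pi))
                        changed = True
    by_met: dict[str, dict[int, set[int]]] = {}
    for c, dests in fate.items():
        for met, idx in dests:
            by_met.setdefault(met, {}).setdefault(c, set()).add(idx)
    fates: dict[str, dict[int, int]] = {}
    ambiguous: set[str] = set()
    for met, per_carbon in by_met.items():
        if any(len(idxs) > 1 for idxs in per_carbon.values()):
            ambiguous.add(met)
            continue
        fates[met] = {c: next(iter(idxs)) for c, idxs in per_carbon.items()}
    return fates, ambiguous


def reaction_carbon_map(
    model: PathwayModel,
    rxn_id: str,
    substrate_ref: str,
    product_ref: str,
) -> dict[int, int]:
    """Atom map of one reaction restricted to a (substrate ref, product ref)
    pair; refs may carry instance suffixes to select a specific copy."""
    r = model.reaction(rxn_id)
    want_s = split_instance(substrate_ref)
    want_p = split_instance(product_ref)
    out: dict[int, int] = {}
    for sm, si, pm, pi in r.atom_map:
        if split_instance(sm) == want_s and split_instance(pm) == want_p:
            out[si] = pi
    return out
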