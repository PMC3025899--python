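"""Phylogeographic inference from nested-clade significance patterns.

The inference key is shipped as an editable JSON decision table (step id,
predicate, yes/no/na transitions) so alternative key versions can be
swapped in; the default encodes the classic 1995 key with its geographic
questions operationalized as computable predicates:

* "occupy geographically distinct areas" → member clades sharing no
  sampled population;
* "deep divergence" → mean mutational steps on network edges between
  member clades exceeding twice the within-clade mean (at least 2);
* sampling-adequacy questions → answered affirmatively.

Conclusions are limited to the enumerated outcomes: restricted gene flow
with isolation by distance, restricted gene flow with some long-distance
dispersal, long-distance colonization, past fragmentation, contiguous
range expansion, and inconclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from ..haplonet import HaplotypeNetwork
from ..seqio import HaplotypeTable
from .geodist import CladeGeoStats, ContingencyResult, InteriorTipContrast
from .nesting import NestingDesign

OUTCOMES = frozenset(
    {
        "restricted gene flow with isolation by distance",
        "restricted gene flow with some long-distance dispersal",
        "long-distance colonization",
        "past fragmentation",
        "contiguous range expansion",
        "inconclusive",
    }
)


def load_inference_key(path=None) -> dict:
    """Load the decision table (default: the packaged 1995-style key)."""
    if path is None:
        ref = resources.files("haplogeo.data").joinpath("inference_key_1995.json")
        key = json.loads(ref.read_text())
    else:
        with open(path) as fh:
            key = json.load(fh)
    for step in key["steps"].values():
        for branch in ("yes", "no", "na"):
            target = step.get(branch)
            if target and target.startswith("conclusion:"):
                concl = target.split(":", 1)[1]
                if concl not in OUTCOMES:
                    raise ValueError(f"unknown conclusion in key: {concl!r}")
    return key


@dataclass
class CladePattern:
    """Everything the key needs to know about one nesting clade."""

    nesting_clade_id: str
    members: list[CladeGeoStats]
    contrast: InteriorTipContrast
    contingency: ContingencyResult | None
    member_pop_counts: dict[str, dict[str, int]]
    inter_steps: list[int]
    intra_steps: list[int]
    alpha: float = 0.05
    # "completely or mostly nonoverlapping": a clade counts as disjoint when
    # at least this fraction of its individuals sit in populations no other
    # member clade occupies
    exclusive_fraction: float = 0.9

    # -- predicate helpers --------------------------------------------------
    def _sig(self, p: float | None) -> bool:
        return p is not None and p <= self.alpha

    def any_significant(self) -> bool:
        for m in self.members:
            if any(
                self._sig(p)
                for p in (m.p_small_Dc, m.p_large_Dc, m.p_small_Dn, m.p_large_Dn)
            ):
                return True
        c = self.contrast
        if c is not None and any(
            self._sig(p)
            for p in (c.p_small_it_Dc, c.p_large_it_Dc, c.p_small_it_Dn, c.p_large_it_Dn)
        ):
            return True
        if self.contingency is not None and self.contingency.applicable:
            if self._sig(self.contingency.p_perm):
                return True
        return False

    def no_tip_interior_distinction(self) -> bool:
        statuses = {m.status for m in self.members}
        return not ({"tip", "interior"} <= statuses)

    def tip_dc_small_or_interior_dc_large(self) -> bool:
        return any(
            (m.status == "tip" and self._sig(m.p_small_Dc))
            or (m.status == "interior" and self._sig(m.p_large_Dc))
            for m in self.members
        )

    def interior_dc_small_or_tip_dc_large(self) -> bool:
        return any(
            (m.status == "interior" and self._sig(m.p_small_Dc))
            or (m.status == "tip" and self._sig(m.p_large_Dc))
            for m in self.members
        )

    def dn_displacement(self) -> bool:
        if any(
            (m.status == "tip" and self._sig(m.p_large_Dn))
            or (m.status == "interior" and self._sig(m.p_small_Dn))
            for m in self.members
        ):
            return True
        return self.contrast is not None and self._sig(self.contrast.p_small_it_Dn)

    def _exclusive_share(self, mid: str, other_pops: frozenset) -> float:
        """Fraction of a member's individuals in populations the given
        other clades do not occupy."""
        counts = self.member_pop_counts[mid]
        total = sum(counts.values())
        if total == 0:
            return 0.0
        exclusive = sum(c for p, c in counts.items() if p not in other_pops)
        return exclusive / total

    def _pops_of(self, mids) -> frozenset:
        return frozenset(
            p
            for mid in mids
            for p, c in self.member_pop_counts[mid].items()
            if c > 0
        )

    def _disjoint_from_rest(self, mid: str) -> bool:
        rest = self._pops_of(
            k for k in self.member_pop_counts if k != mid
        )
        return self._exclusive_share(mid, rest) >= self.exclusive_fraction

    def some_member_disjoint(self) -> bool:
        return any(self._disjoint_from_rest(m.clade_id) for m in self.members)

    def all_members_disjoint(self) -> bool:
        return all(self._disjoint_from_rest(m.clade_id) for m in self.members)

    def tips_disjoint_from_interiors(self) -> bool:
        tips = [m.clade_id for m in self.members if m.status == "tip"]
        interiors = [m.clade_id for m in self.members if m.status == "interior"]
        if not tips or not interiors:
            return False
        int_pops = self._pops_of(interiors)
        shares = [self._exclusive_share(t, int_pops) for t in tips]
        return min(shares) >= self.exclusive_fraction

    def deep_divergence(self) -> bool:
        if not self.inter_steps:
            return False
        mean_inter = sum(self.inter_steps) / len(self.inter_steps)
        mean_intra = (
            sum(self.intra_steps) / len(self.intra_steps)
            if self.intra_steps
            else 1.0
        )
        return mean_inter > 2.0 * max(1.0, mean_intra)


@dataclass
class InferenceOutcome:
    clade_id: str
    key_path: list[tuple[str, str]] = field(default_factory=list)
    conclusion: str = "inconclusive"

    def chain(self) -> str:
        steps = "-".join(f"{s}({a})" for s, a in self.key_path)
        return f"{steps} -> {self.conclusion}"


def apply_inference_key(
    pattern: CladePattern, key: dict | None = None
) -> InferenceOutcome:
    """Deterministically traverse the decision table for one nesting clade.

    Patterns that fall outside the table (missing predicates or dangling
    transitions) end as ``inconclusive`` with the partial path recorded.
    """
    if key is None:
        key = load_inference_key()
    out = InferenceOutcome(clade_id=pattern.nesting_clade_id)
    step_id = key["start"]
    for _ in range(len(key["steps"]) + 1):
        step = key["steps"].get(step_id)
        if step is None:
            break  # dangling transition: record partial path, stay inconclusive
        na_pred = step.get("na_predicate")
        if na_pred is not None and getattr(pattern, na_pred)():
            out.key_path.append((step_id, "na"))
            target = step["na"]
        else:
            pred = getattr(pattern, step["predicate"], None)
            if pred is None:
                break
            answer = "yes" if pred() else "no"
            out.key_path.append((step_id, answer))
            target = step[answer]
        if target.startswith("conclusion:"):
            out.conclusion = target.split(":", 1)[1]
            return out
        step_id = target
    out.conclusion = "inconclusive"
    return out


def build_patterns(
    design: NestingDesign,
    stats: dict[str, CladeGeoStats],
    contrasts: dict[str, InteriorTipContrast],
    contingency: dict[str, ContingencyResult],
    table: HaplotypeTable,
    network: HaplotypeNetwork,
    alpha: float = 0.05,
) -> dict[str, CladePattern]:
    """Assemble the per-nesting-clade significance patterns the key consumes."""
    patterns: dict[str, CladePattern] = {}
    for parent in design.clades:
        member_ids = [m for m in parent.members if m in stats]
        if len(member_ids) < 2:
            continue
        hap_to_member: dict[str, str] = {}
        member_pop_counts: dict[str, dict[str, int]] = {}
        for mid in member_ids:
            haps = [
                h for h in design.haplotypes_of(mid) if h in table.counts.index
            ]
            for h in haps:
                hap_to_member[h] = mid
            counts = table.counts.loc[haps].sum(axis=0)
            member_pop_counts[mid] = {
                p: int(counts[p]) for p in counts.index if counts[p] > 0
            }
        inter, intra = [], []
        for u, v, data in network.graph.edges(data=True):
            mu, mv = hap_to_member.get(u), hap_to_member.get(v)
            if mu is None or mv is None:
                continue
            (inter if mu != mv else intra).append(int(data["steps"]))
        patterns[parent.clade_id] = CladePattern(
            nesting_clade_id=parent.clade_id,
            members=[stats[m] for m in member_ids],
            contrast=contrasts.get(parent.clade_id),
            contingency=contingency.get(parent.clade_id),
            member_pop_counts=member_pop_counts,
            inter_steps=inter,
            intra_steps=intra,
            alpha=alpha,
        )
    return patterns


def infer_all(
    design: NestingDesign,
    stats: dict[str, CladeGeoStats],
    contrasts: dict[str, InteriorTipContrast],
    contingency: dict[str, ContingencyResult],
    table: HaplotypeTable,
    network: HaplotypeNetwork,
    alpha: float = 0.05,
    key: dict | None = None,
) -> dict[str, InferenceOutcome]:
    """Apply the key to every nesting clade with at least two members."""
    if key is None:
        key = load_inference_key()
    patterns = build_patterns(
        design, stats, contrasts, contingency, table, network, alpha
    )
    return {
        pid: apply_inference_key(pat, key) for pid, pat in patterns.items()
    }
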