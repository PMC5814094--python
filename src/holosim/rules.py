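"""Site-level reaction rules and the lookup table that replaces network
expansion.

Molecules are declared with named binary sites (binding sites carry a bond;
flag sites such as phosphorylation do not).  Reactions are written one per
line in a small textual dialect::

    cam{C1==0, C2==0, k==0} + ca{b==0} <-> cam~ca{cam.C1=1, ca.b=1} kf=10 kb=40 label=C1~ca
    CaL{gate==0} <-> CaL{gate=1} kf=ro kb=rc

``==`` tests a site state on the left-hand side, ``=`` assigns on the right;
``+`` separates the reactants of a bimolecular rule and ``~`` marks the bound
product.  Rates may be numeric literals or symbolic names resolved against a
rate dictionary.  Condition targets may be qualified (``partner.site``,
``left.site``, ``right.site``) — neighbor targets are only meaningful for
molecules living in ring complexes.

Instead of expanding the reaction network into concrete species, rules are
stored in a table keyed by the reactant types and their full binary state
vectors.  During a simulation, a colliding pair is resolved by a single
lookup; when several rules share the same reactant pair (branched binding),
the combined forward rate is the sum of the branch rates and a single
uniform draw selects the branch proportionally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SiteType",
    "MoleculeType",
    "SiteCondition",
    "SiteAssignment",
    "ReactantPattern",
    "ReactionRule",
    "RuleParseError",
    "parse_rule",
    "parse_rules",
    "serialize_rule",
    "RuleTable",
    "combined_rate",
    "select_branch",
]

_IDENT = r"[A-Za-z_][A-Za-z0-9_']*"


class RuleParseError(ValueError):
    def __init__(self, msg: str, line: int | None = None, col: int | None = None):
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", col {col}" if col is not None else "") + ")"
        super().__init__(msg + loc)
        self.line = line
        self.col = col


@dataclass(frozen=True)
class SiteType:
    """A binary site on a molecule: a binding site or a flag."""

    name: str
    kind: str = "binding"  # "binding" | "flag"
    default_state: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("binding", "flag"):
            raise ValueError(f"unknown site kind {self.kind!r}")
        if self.default_state not in (0, 1):
            raise ValueError("site states are strictly binary")


@dataclass(frozen=True)
class MoleculeType:
    """A molecule type with named binary sites and a diffusion coefficient."""

    name: str
    sites: tuple[SiteType, ...]
    diffusion_cm2_s: float = 0.0
    mobile: bool = True

    def __post_init__(self) -> None:
        if self.diffusion_cm2_s < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        names = [s.name for s in self.sites]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate site names in molecule {self.name}")

    @property
    def diffusion_um2_s(self) -> float:
        if not self.mobile:
            return 0.0
        return self.diffusion_cm2_s * 1e8

    @property
    def site_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sites)

    def site_index(self, name: str) -> int:
        try:
            return self.site_names.index(name)
        except ValueError:
            raise KeyError(f"molecule {self.name} has no site {name!r}") from None

    def default_state_vector(self) -> np.ndarray:
        return np.array([s.default_state for s in self.sites], dtype=np.uint8)


@dataclass(frozen=True)
class SiteCondition:
    """``target.site == value`` on a rule's left-hand side."""

    site: str
    value: int
    target: str = "self"  # self | partner | left | right

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError("site states are strictly binary")
        if self.target not in ("self", "partner", "left", "right"):
            raise ValueError(f"unknown condition target {self.target!r}")


@dataclass(frozen=True)
class SiteAssignment:
    """``target.site = value`` on a rule's right-hand side.

    For order-2 rules the target names the reactant (by molecule-type name);
    for order-1 rules it is "self".
    """

    site: str
    value: int
    target: str = "self"

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError("site states are strictly binary")


@dataclass(frozen=True)
class ReactantPattern:
    molecule: str
    conditions: tuple[SiteCondition, ...] = ()


@dataclass(frozen=True)
class ReactionRule:
    """A reversible site-level rule.

    ``k_f`` is in uM^-1 s^-1 for order-2 rules and s^-1 for order-1 rules;
    ``k_b`` is always s^-1.  ``label`` names the network edge (the event log
    appends "+"/"-" for the two directions).
    """

    order: int
    reactants: tuple[ReactantPattern, ...]
    assignments: tuple[SiteAssignment, ...]
    k_f: float
    k_b: float
    label: str
    k_f_name: str | None = None
    k_b_name: str | None = None

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValueError("rule order must be 1 or 2")
        if len(self.reactants) != self.order:
            raise ValueError("reactant count must match rule order")
        if self.k_f < 0 or self.k_b < 0:
            raise ValueError("rates must be >= 0")

    def bond_sites(self, molecules: dict[str, MoleculeType]) -> tuple[str, str] | None:
        """For a binding rule, the (siteA, siteB) pair the bond lives on.

        A binding rule must set exactly one binding-kind site on each
        reactant; returns None for order-1 rules.
        """
        if self.order != 2:
            return None
        per_reactant: list[list[str]] = [[], []]
        for a in self.assignments:
            for i, rp in enumerate(self.reactants):
                if a.target in (rp.molecule, f"r{i}"):
                    mol = molecules[rp.molecule]
                    st = mol.sites[mol.site_index(a.site)]
                    if st.kind == "binding" and a.value == 1:
                        per_reactant[i].append(a.site)
        if len(per_reactant[0]) != 1 or len(per_reactant[1]) != 1:
            raise ValueError(
                f"binding rule {self.label!r} must set exactly one bond site "
                f"on each reactant")
        return per_reactant[0][0], per_reactant[1][0]


# ---------------------------------------------------------------------------
# parsing


def _parse_brace_items(body: str, op: str, line_no: int, col0: int):
    """Split '{a==1, b.c=0}'-style bodies; op is '==' or '='."""
    other = "=" if op == "==" else "=="
    items = []
    body = body.strip()
    if not body:
        return items
    for raw in body.split(","):
        tok = raw.strip()
        if not tok:
            continue
        if op == "=" and "==" in tok:
            raise RuleParseError(
                f"'==' used on right-hand side in {tok!r}", line_no, col0)
        if op == "==" and ("==" not in tok and "=" in tok):
            raise RuleParseError(
                f"'=' used on left-hand side in {tok!r}", line_no, col0)
        if op not in tok:
            raise RuleParseError(f"expected {op!r} in {tok!r}", line_no, col0)
        lhs, _, rhs = tok.partition(op)
        lhs, rhs = lhs.strip(), rhs.strip()
        if rhs not in ("0", "1"):
            raise RuleParseError(
                f"site states are binary, got {rhs!r} in {tok!r}", line_no, col0)
        if "." in lhs:
            target, _, site = lhs.partition(".")
        else:
            target, site = "self", lhs
        if not re.fullmatch(_IDENT, site) or not re.fullmatch(_IDENT, target):
            raise RuleParseError(f"bad site reference {lhs!r}", line_no, col0)
        items.append((target, site, int(rhs)))
    return items


_PATTERN_RE = re.compile(rf"\s*({_IDENT})\s*(?:\{{([^}}]*)\}})?\s*$")
_RATE_RE = re.compile(
    rf"kf\s*=\s*(?P<kf>\S+)\s+kb\s*=\s*(?P<kb>\S+)(?:\s+label\s*=\s*(?P<label>\S+))?\s*$")


def _resolve_rate(tok: str, rates: dict[str, float] | None, line_no: int):
    try:
        return float(tok), None
    except ValueError:
        pass
    if not re.fullmatch(_IDENT, tok):
        raise RuleParseError(f"bad rate value {tok!r}", line_no)
    if rates is None or tok not in rates:
        raise RuleParseError(f"unknown rate symbol {tok!r}", line_no)
    return float(rates[tok]), tok


def parse_rule(text: str, molecules: dict[str, MoleculeType] | None = None,
               rates: dict[str, float] | None = None,
               line_no: int = 1) -> ReactionRule:
    """Parse a single rule line into a canonical :class:`ReactionRule`.

    ``molecules`` enables molecule/site validation; ``rates`` resolves
    symbolic rate names.  Raises :class:`RuleParseError` with position
    information on malformed input.
    """
    line = text.strip()
    if "<->" not in line:
        raise RuleParseError("missing '<->'", line_no)
    lhs_txt, _, rest = line.partition("<->")
    m = _RATE_RE.search(rest)
    if m is None:
        raise RuleParseError("missing 'kf=... kb=...' rate clause", line_no)
    rhs_txt = rest[: m.start()].strip()
    k_f, kf_name = _resolve_rate(m.group("kf"), rates, line_no)
    k_b, kb_name = _resolve_rate(m.group("kb"), rates, line_no)

    parts = [p for p in lhs_txt.split("+")]
    if len(parts) not in (1, 2):
        raise RuleParseError("a rule has one or two reactants", line_no)
    reactants = []
    for p in parts:
        pm = _PATTERN_RE.match(p)
        if pm is None:
            raise RuleParseError(f"bad reactant pattern {p.strip()!r}", line_no)
        mol_name, cond_body = pm.group(1), pm.group(2) or ""
        conds = tuple(sorted(
            (SiteCondition(site=s, value=v, target=t)
             for t, s, v in _parse_brace_items(
                 cond_body, "==", line_no, pm.start(2) if pm.group(2) else 0)),
            key=lambda c: (c.target, c.site)))
        reactants.append(ReactantPattern(mol_name, conds))
    order = len(reactants)

    # right-hand side: product name(s) ~-joined, then assignment braces
    rm = re.match(rf"\s*({_IDENT})(?:\s*~\s*({_IDENT}))?\s*\{{([^}}]*)\}}\s*$", rhs_txt)
    if rm is None:
        raise RuleParseError(f"bad product pattern {rhs_txt!r}", line_no)
    prod_names = [n for n in (rm.group(1), rm.group(2)) if n]
    if order == 2 and len(prod_names) != 2:
        raise RuleParseError("bimolecular product must be written A~B{...}", line_no)
    reactant_names = [r.molecule for r in reactants]
    if sorted(prod_names) != sorted(reactant_names):
        raise RuleParseError(
            f"product molecules {prod_names} do not match reactants "
            f"{reactant_names}", line_no)
    raw_assigns = _parse_brace_items(rm.group(3), "=", line_no, 0)
    assignments = []
    for t, s, v in raw_assigns:
        if order == 1:
            if t not in ("self", reactants[0].molecule):
                raise RuleParseError(f"unknown assignment target {t!r}", line_no)
            assignments.append(SiteAssignment(site=s, value=v, target="self"))
        else:
            if t == "self":
                raise RuleParseError(
                    "bimolecular assignments must be qualified (A.site=1)", line_no)
            if t not in reactant_names:
                raise RuleParseError(f"unknown assignment target {t!r}", line_no)
            assignments.append(SiteAssignment(site=s, value=v, target=t))
    if not assignments:
        raise RuleParseError("rule assigns nothing", line_no)
    assignments.sort(key=lambda a: (a.target, a.site))

    label = m.group("label") or _default_label(reactants, assignments)
    rule = ReactionRule(order=order, reactants=tuple(reactants),
                        assignments=tuple(assignments), k_f=k_f, k_b=k_b,
                        label=label, k_f_name=kf_name, k_b_name=kb_name)
    if molecules is not None:
        _validate_rule(rule, molecules, line_no)
    return rule


def _default_label(reactants, assignments) -> str:
    names = "~".join(r.molecule for r in reactants)
    assigns = ",".join(f"{a.target}.{a.site}={a.value}" for a in assignments)
    return f"{names}[{assigns}]"


def _validate_rule(rule: ReactionRule, molecules: dict[str, MoleculeType],
                   line_no: int) -> None:
    by_name = {r.molecule: r for r in rule.reactants}
    for rp in rule.reactants:
        if rp.molecule not in molecules:
            raise RuleParseError(f"unknown molecule {rp.molecule!r}", line_no)
        mol = molecules[rp.molecule]
        for c in rp.conditions:
            if c.target == "self":
                mol.site_index(c.site)
            elif c.target == "partner":
                if rule.order != 2:
                    raise RuleParseError(
                        "partner condition in unimolecular rule", line_no)
                other = next(r for r in rule.reactants if r is not rp)
                molecules[other.molecule].site_index(c.site)
            else:  # left/right checked against the molecule's own sites
                mol.site_index(c.site)
    for a in rule.assignments:
        mol = molecules[rule.reactants[0].molecule if a.target == "self" else a.target]
        mol.site_index(a.site)
    if rule.order == 2:
        rule.bond_sites(molecules)


def parse_rules(text: str, molecules: dict[str, MoleculeType] | None = None,
                rates: dict[str, float] | None = None) -> list[ReactionRule]:
    """Parse a rule file: one rule per line, ``#`` comments, blank lines ok."""
    out = []
    for i, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        out.append(parse_rule(stripped, molecules, rates, line_no=i))
    return out


def serialize_rule(rule: ReactionRule) -> str:
    """Canonical textual form; ``parse(serialize(parse(x)))`` is the identity."""

    def fmt_conds(conds):
        items = []
        for c in sorted(conds, key=lambda c: (c.target, c.site)):
            prefix = "" if c.target == "self" else f"{c.target}."
            items.append(f"{prefix}{c.site}=={c.value}")
        return "{" + ", ".join(items) + "}"

    lhs = " + ".join(f"{r.molecule}{fmt_conds(r.conditions)}" for r in rule.reactants)
    prod = "~".join(r.molecule for r in rule.reactants)
    assigns = ", ".join(
        (f"{a.site}={a.value}" if a.target == "self" else f"{a.target}.{a.site}={a.value}")
        for a in sorted(rule.assignments, key=lambda a: (a.target, a.site)))
    kf = rule.k_f_name or f"{rule.k_f:g}"
    kb = rule.k_b_name or f"{rule.k_b:g}"
    return f"{lhs} <-> {prod}{{{assigns}}} kf={kf} kb={kb} label={rule.label}"


# ---------------------------------------------------------------------------
# rule table


def combined_rate(candidates: list[ReactionRule]) -> float:
    """Total forward rate of a branched binding scheme (sum of branch kf)."""
    return float(sum(r.k_f for r in candidates))


def select_branch(candidates: list[ReactionRule], u: float) -> ReactionRule:
    """Pick the branch whose subinterval of (0, 1] contains ``u``.

    The unit interval is partitioned proportionally to the branch forward
    rates, in the table's deterministic (label-sorted) candidate order.
    """
    if not candidates:
        raise ValueError("no candidate rules")
    if not (0.0 < u <= 1.0):
        raise ValueError("u must be in (0, 1]")
    total = combined_rate(candidates)
    if total <= 0.0:
        raise ValueError("all branch rates are zero; no reaction")
    acc = 0.0
    for rule in candidates:
        acc += rule.k_f / total
        if u <= acc + 1e-15:
            return rule
    return candidates[-1]


def conditions_hold(conds: tuple[SiteCondition, ...], mol: MoleculeType,
                    state: np.ndarray,
                    partner_mol: MoleculeType | None = None,
                    partner_state: np.ndarray | None = None) -> bool:
    """Evaluate self/partner conditions against concrete state vectors.

    Neighbor (left/right) conditions are resolved by the engine's ring
    machinery, not here; they evaluate False outside a ring context.
    """
    for c in conds:
        if c.target == "self":
            if state[mol.site_index(c.site)] != c.value:
                return False
        elif c.target == "partner":
            if partner_state is None or partner_mol is None:
                return False
            if partner_state[partner_mol.site_index(c.site)] != c.value:
                return False
        else:
            return False
    return True


class RuleTable:
    """Hash-table lookup of candidate rules by reactant types and states.

    Keys are ``(type_a, state_a_bytes, type_b, state_b_bytes)`` with the pair
    in both orders, built lazily; a lookup is guaranteed to return all and
    only the rules whose conditions hold for the concrete states (the same
    answer a brute-force scan over all rules gives), with candidates in
    deterministic label order so branch selection is reproducible.
    """

    def __init__(self, rules: list[ReactionRule],
                 molecules: dict[str, MoleculeType]):
        labels = [r.label for r in rules]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate rule labels: {dup}")
        for i, a in enumerate(rules):
            for b in rules[i + 1:]:
                if (a.order == b.order and a.reactants == b.reactants
                        and a.assignments == b.assignments):
                    raise ValueError(
                        f"rules {a.label!r} and {b.label!r} are identical")
        self.molecules = molecules
        self.rules = sorted(rules, key=lambda r: r.label)
        self.binary = [r for r in self.rules if r.order == 2]
        self.unary = [r for r in self.rules if r.order == 1]
        self._cache: dict[tuple, tuple[list[ReactionRule], float]] = {}
        self.pair_types: set[frozenset[str]] = {
            frozenset(r.molecule for r in rule.reactants) for rule in self.binary}

    def scan(self, type_a: str, state_a: np.ndarray,
             type_b: str, state_b: np.ndarray) -> list[ReactionRule]:
        """Brute-force condition evaluation over all order-2 rules."""
        mols = self.molecules
        out = []
        for rule in self.binary:
            r0, r1 = rule.reactants
            orientations = []
            if (r0.molecule, r1.molecule) == (type_a, type_b):
                orientations.append((r0, state_a, r1, state_b))
            if type_a != type_b and (r0.molecule, r1.molecule) == (type_b, type_a):
                orientations.append((r0, state_b, r1, state_a))
            for pa, sa, pb, sb in orientations:
                ma, mb = mols[pa.molecule], mols[pb.molecule]
                if (conditions_hold(pa.conditions, ma, sa, mb, sb)
                        and conditions_hold(pb.conditions, mb, sb, ma, sa)):
                    out.append(rule)
                    break
        return out

    def lookup(self, type_a: str, state_a: np.ndarray,
               type_b: str, state_b: np.ndarray) -> tuple[list[ReactionRule], float]:
        """Candidate rules and their combined forward rate for a state pair."""
        key = (type_a, state_a.tobytes(), type_b, state_b.tobytes())
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        cands = self.scan(type_a, state_a, type_b, state_b)
        entry = (cands, combined_rate(cands))
        self._cache[key] = entry
        self._cache[(type_b, state_b.tobytes(), type_a, state_a.tobytes())] = entry
        return entry


def build_table(rules: list[ReactionRule],
                molecules: dict[str, MoleculeType]) -> RuleTable:
    """Validate rules against molecule declarations and build the table."""
    for rule in rules:
        _validate_rule(rule, molecules, line_no=0)
    return RuleTable(rules, molecules)
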