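"""In-paper fixtures and a seeded random-mechanism generator.

Two kinds of test material are produced here, both without any external
download:

* hand-encoded curly-arrow mechanisms of the retaining-glycosidase
  double-displacement pair (an alpha-amylase and an endo-xyloglucan
  transferase) whose two-away arrow-env and chain cardinalities are the
  published worked example (6 and 6 envs with intersection 4; 4 and 4
  chains with intersection 2), self-checked at construction time;
* seeded random synthetic mechanisms for property and corpus-scale
  tests, with defaults shaped like a curated mechanism corpus (about
  2-6 steps per mechanism and 3-9 arrows per step over C/H/O/N/S/P
  chemistry).
"""

from __future__ import annotations

import copy
import random
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

from .arrowenv import TWO_AWAY
from .errors import GeneratorError
from .model import (
    ActiveSiteState,
    ArrowEndpoint,
    AtomNode,
    BondEdge,
    BondOrder,
    CatalyticStep,
    CurlyArrow,
    Mechanism,
    reaction_centres,
    validate_mechanism,
)

C, H, O, N, S, P = 6, 1, 8, 7, 16, 15


class _StateBuilder:
    """Incremental construction of an active-site state."""

    def __init__(self) -> None:
        self.atoms: list[AtomNode] = []
        self.bonds: list[BondEdge] = []

    def add(self, atom_id: int, element: int, charge: int = 0) -> int:
        self.atoms.append(AtomNode(atom_id, element, charge))
        return atom_id

    def bond(self, a: int, b: int, order: BondOrder = BondOrder.SINGLE) -> None:
        self.bonds.append(BondEdge(a, b, order))

    def build(self) -> ActiveSiteState:
        return ActiveSiteState(tuple(self.atoms), tuple(self.bonds))


# ---------------------------------------------------------------------------
# Glycosidase fixtures
#
# Step 1 (glycosylation, shared chemistry of both enzymes): the aspartate
# carboxylate oxygen attacks the anomeric carbon, the glycosidic C-O bond
# swings onto the acidic proton of the glutamate, and the glutamate O-H
# bond collapses onto its oxygen — a single concerted chain of three
# arrows.  Step 2 differs between the enzymes only in the incoming
# nucleophile: water (hydrolysis, alpha-amylase) versus a sugar hydroxyl
# (transglycosylation, endo-xyloglucan transferase; the acceptor-glucan
# hydroxyl was chosen as the attacking group).

# step-1 atom ids
_O_NUC, _C_CX, _O_CX2, _C_B, _H_B1, _H_B2 = 1, 2, 3, 4, 5, 6
_C1, _O5, _C2, _H1, _O_GLYC, _C_AGL, _C5 = 10, 11, 12, 13, 14, 15, 16
_H2, _O2, _H_O2, _C3, _H_AGL, _C_AGL2, _H5A, _H5B = 17, 18, 19, 20, 21, 22, 24, 25
_O_AC, _H_AC, _C_ACX, _O_ACX2, _C_BG, _H_BG1, _H_BG2 = 30, 31, 32, 33, 34, 35, 36


def _glycosylation_step() -> CatalyticStep:
    b = _StateBuilder()
    # aspartate nucleophile (deprotonated carboxylate)
    b.add(_O_NUC, O, -1)
    b.add(_C_CX, C)
    b.add(_O_CX2, O)
    b.add(_C_B, C)
    b.add(_H_B1, H)
    b.add(_H_B2, H)
    b.bond(_O_NUC, _C_CX)
    b.bond(_C_CX, _O_CX2, BondOrder.DOUBLE)
    b.bond(_C_CX, _C_B)
    b.bond(_C_B, _H_B1)
    b.bond(_C_B, _H_B2)
    # glucosyl unit around the anomeric carbon, plus the aglycone carbon
    b.add(_C1, C)
    b.add(_O5, O)
    b.add(_C2, C)
    b.add(_H1, H)
    b.add(_O_GLYC, O)
    b.add(_C_AGL, C)
    b.add(_C5, C)
    b.add(_H2, H)
    b.add(_O2, O)
    b.add(_H_O2, H)
    b.add(_C3, C)
    b.add(_H_AGL, H)
    b.add(_C_AGL2, C)
    b.add(_H5A, H)
    b.add(_H5B, H)
    b.bond(_C1, _O5)
    b.bond(_C1, _C2)
    b.bond(_C1, _H1)
    b.bond(_C1, _O_GLYC)
    b.bond(_O5, _C5)
    b.bond(_C2, _H2)
    b.bond(_C2, _O2)
    b.bond(_C2, _C3)
    b.bond(_O2, _H_O2)
    b.bond(_O_GLYC, _C_AGL)
    b.bond(_C_AGL, _H_AGL)
    b.bond(_C_AGL, _C_AGL2)
    b.bond(_C5, _H5A)
    b.bond(_C5, _H5B)
    # glutamate general acid
    b.add(_O_AC, O)
    b.add(_H_AC, H)
    b.add(_C_ACX, C)
    b.add(_O_ACX2, O)
    b.add(_C_BG, C)
    b.add(_H_BG1, H)
    b.add(_H_BG2, H)
    b.bond(_O_AC, _H_AC)
    b.bond(_O_AC, _C_ACX)
    b.bond(_C_ACX, _O_ACX2, BondOrder.DOUBLE)
    b.bond(_C_ACX, _C_BG)
    b.bond(_C_BG, _H_BG1)
    b.bond(_C_BG, _H_BG2)
    arrows = (
        # carboxylate lone pair attacks the anomeric carbon
        CurlyArrow(2, ArrowEndpoint.atom(_O_NUC), ArrowEndpoint.incipient(_O_NUC, _C1)),
        # glycosidic bond swings onto the acidic proton
        CurlyArrow(
            2, ArrowEndpoint.bond(_C1, _O_GLYC), ArrowEndpoint.incipient(_O_GLYC, _H_AC)
        ),
        # acid O-H bond collapses onto the acid oxygen
        CurlyArrow(2, ArrowEndpoint.bond(_O_AC, _H_AC), ArrowEndpoint.atom(_O_AC)),
    )
    return CatalyticStep(1, b.build(), arrows)


# step-2 ids for the covalent glycosyl-enzyme + general base
_W_O, _W_H1, _W_H2 = 40, 41, 42
_S_O, _S_H, _S_C, _S_HC, _S_C2 = 40, 41, 43, 44, 45


def _glycosyl_enzyme(b: _StateBuilder) -> None:
    """Covalent intermediate and deprotonated glutamate shared by both
    second steps."""
    b.add(_O_NUC, O)  # now the neutral ester oxygen
    b.add(_C_CX, C)
    b.add(_O_CX2, O)
    b.add(_C_B, C)
    b.add(_H_B1, H)
    b.add(_H_B2, H)
    b.bond(_O_NUC, _C_CX)
    b.bond(_C_CX, _O_CX2, BondOrder.DOUBLE)
    b.bond(_C_CX, _C_B)
    b.bond(_C_B, _H_B1)
    b.bond(_C_B, _H_B2)
    b.add(_C1, C)
    b.add(_O5, O)
    b.add(_C2, C)
    b.add(_H1, H)
    b.add(_C5, C)
    b.add(_H2, H)
    b.add(_O2, O)
    b.add(_H_O2, H)
    b.add(_C3, C)
    b.add(_H5A, H)
    b.add(_H5B, H)
    b.bond(_C1, _O_NUC)
    b.bond(_C1, _O5)
    b.bond(_C1, _C2)
    b.bond(_C1, _H1)
    b.bond(_O5, _C5)
    b.bond(_C2, _H2)
    b.bond(_C2, _O2)
    b.bond(_C2, _C3)
    b.bond(_O2, _H_O2)
    b.bond(_C5, _H5A)
    b.bond(_C5, _H5B)
    # glutamate, deprotonated after step 1, now the general base
    b.add(_O_AC, O, -1)
    b.add(_C_ACX, C)
    b.add(_O_ACX2, O)
    b.add(_C_BG, C)
    b.add(_H_BG1, H)
    b.add(_H_BG2, H)
    b.bond(_O_AC, _C_ACX)
    b.bond(_C_ACX, _O_ACX2, BondOrder.DOUBLE)
    b.bond(_C_ACX, _C_BG)
    b.bond(_C_BG, _H_BG1)
    b.bond(_C_BG, _H_BG2)


def _deglycosylation_arrows(nuc_o: int, nuc_h: int) -> tuple[CurlyArrow, ...]:
    return (
        # incoming nucleophile attacks the anomeric carbon
        CurlyArrow(2, ArrowEndpoint.atom(nuc_o), ArrowEndpoint.incipient(nuc_o, _C1)),
        # the ester C-O bond returns to the carboxylate oxygen
        CurlyArrow(2, ArrowEndpoint.bond(_C1, _O_NUC), ArrowEndpoint.atom(_O_NUC)),
        # the base abstracts the nucleophile's proton
        CurlyArrow(
            2, ArrowEndpoint.bond(nuc_o, nuc_h), ArrowEndpoint.incipient(nuc_h, _O_AC)
        ),
    )


def _hydrolysis_step() -> CatalyticStep:
    b = _StateBuilder()
    _glycosyl_enzyme(b)
    b.add(_W_O, O)
    b.add(_W_H1, H)
    b.add(_W_H2, H)
    b.bond(_W_O, _W_H1)
    b.bond(_W_O, _W_H2)
    return CatalyticStep(2, b.build(), _deglycosylation_arrows(_W_O, _W_H1))


def _transglycosylation_step() -> CatalyticStep:
    b = _StateBuilder()
    _glycosyl_enzyme(b)
    b.add(_S_O, O)
    b.add(_S_H, H)
    b.add(_S_C, C)
    b.add(_S_HC, H)
    b.add(_S_C2, C)
    b.bond(_S_O, _S_H)
    b.bond(_S_O, _S_C)
    b.bond(_S_C, _S_HC)
    b.bond(_S_C, _S_C2)
    return CatalyticStep(2, b.build(), _deglycosylation_arrows(_S_O, _S_H))


@lru_cache(maxsize=1)
def _glycosidase_pair() -> tuple[Mechanism, Mechanism]:
    amylase = Mechanism(
        "alpha_amylase",
        (_glycosylation_step(), _hydrolysis_step()),
        annotations={"ec": ["3.2.1.1"], "cath": ["3.20.20.80"]},
    )
    xet = Mechanism(
        "xyloglucan_transferase",
        (replace(_glycosylation_step(), step_index=1), _transglycosylation_step()),
        annotations={"ec": ["2.4.1.207"], "cath": ["2.60.120.200"]},
    )
    _self_check(amylase, xet)
    return amylase, xet


def _self_check(a: Mechanism, b: Mechanism) -> None:
    """Fail loudly if the encoded chemistry drifts from the published
    worked-example cardinalities."""
    from .similarity import mechanism_chains, mechanism_envs, similarity_unordered

    for mech in (a, b):
        bad = validate_mechanism(mech)
        if bad:
            raise RuntimeError(f"fixture {mech.mechanism_id} invalid: {bad}")
    envs_a, envs_b = mechanism_envs(a, TWO_AWAY), mechanism_envs(b, TWO_AWAY)
    ch_a, ch_b = mechanism_chains(a, TWO_AWAY), mechanism_chains(b, TWO_AWAY)
    cards = (
        len(envs_a), len(envs_b), len(envs_a & envs_b),
        len(ch_a), len(ch_b), len(ch_a & ch_b),
    )
    if cards != (6, 6, 4, 4, 4, 2):
        raise RuntimeError(
            f"glycosidase fixture cardinalities drifted: got {cards}, "
            "expected (6, 6, 4, 4, 4, 2)"
        )
    if similarity_unordered(a.steps[0], b.steps[0], TWO_AWAY).value != 1.0:
        raise RuntimeError("glycosidase fixture first steps are no longer identical")


def make_glycosidase_pair() -> tuple[Mechanism, Mechanism]:
    """The worked-example pair: alpha-amylase (hydrolysis) and
    endo-xyloglucan transferase (transglycosylation), two steps of three
    arrows each.  Construction self-checks the two-away cardinalities
    (6/6 envs with intersection 4; 4/4 chains with intersection 2)."""
    return _glycosidase_pair()


def make_fig1_step() -> CatalyticStep:
    """The glycosylation step alone: a linear chain of three arrows whose
    first arrow's one-away env serializes to
    ``[#6]-[#8&-:23].[#8]-[#6:22](-[#8])(-[#1])-[#6]``."""
    return _glycosylation_step()


BUNDLED_FIXTURES = (
    "alpha_amylase",
    "xyloglucan_transferase",
    "glycosylation_step",
)


def load_bundled(name: str) -> Mechanism:
    """Load one of the fixture mechanisms shipped as JSON package data.

    The files are byte-identical to what the constructors above produce;
    the test suite enforces the agreement.
    """
    from importlib.resources import files

    from .formats import parse_mechanism_json

    if name not in BUNDLED_FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {BUNDLED_FIXTURES}")
    text = files("mechsim.data").joinpath(f"{name}.json").read_text()
    return parse_mechanism_json(text)


# ---------------------------------------------------------------------------
# Random generator

_DEFAULT_ELEMENTS: tuple[tuple[int, float], ...] = (
    (C, 0.40),
    (O, 0.28),
    (N, 0.18),
    (S, 0.07),
    (P, 0.07),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-mechanism generator.

    Ranges are inclusive.  Defaults emulate a curated mechanism corpus:
    a handful of steps per mechanism, several concerted arrows per step,
    active sites of one to three species built from organic/biological
    elements, occasional formal charges, and a mix of bond-sourced and
    lone-pair-sourced arrows.
    """

    seed: int = 0
    n_steps: tuple[int, int] = (2, 6)
    arrows_per_step: tuple[int, int] = (3, 9)
    atoms_per_state: tuple[int, int] = (14, 26)
    elements: tuple[tuple[int, float], ...] = _DEFAULT_ELEMENTS
    h_fraction: float = 0.35
    charge_prob: float = 0.08
    bond_source_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_steps", "arrows_per_step", "atoms_per_state"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise GeneratorError(f"{name} range ({lo},{hi}) is empty or invalid")
        for p in (self.h_fraction, self.charge_prob, self.bond_source_fraction):
            if not 0.0 <= p <= 1.0:
                raise GeneratorError(f"probability {p} outside [0,1]")
        if not self.elements or any(w < 0 for _, w in self.elements):
            raise GeneratorError("element palette must be nonempty with weights >= 0")
        if self.atoms_per_state[0] < 4:
            raise GeneratorError(
                "atoms_per_state minimum must be >= 4 so arrows can always "
                "find distinct source and sink atoms"
            )


def _random_state(rng: random.Random, cfg: GeneratorConfig) -> ActiveSiteState:
    n_atoms = rng.randint(*cfg.atoms_per_state)
    n_heavy = max(3, n_atoms - int(round(n_atoms * cfg.h_fraction)))
    zs = [z for z, _ in cfg.elements]
    ws = [w for _, w in cfg.elements]
    b = _StateBuilder()
    # 1-3 species, each a random tree over heavy atoms
    n_species = rng.randint(1, min(3, n_heavy // 2))
    sizes = [1] * n_species
    for _ in range(n_heavy - n_species):
        sizes[rng.randrange(n_species)] += 1
    next_id = 1
    species_atoms: list[list[int]] = []
    for size in sizes:
        members: list[int] = []
        for k in range(size):
            z = rng.choices(zs, weights=ws)[0]
            charge = 0
            if z != C and rng.random() < cfg.charge_prob:
                charge = rng.choice([-1, 1])
            aid = b.add(next_id, z, charge)
            next_id += 1
            if members:
                anchor = rng.choice(members)
                order = (
                    BondOrder.DOUBLE if rng.random() < 0.12 else BondOrder.SINGLE
                )
                b.bond(anchor, aid, order)
            members.append(aid)
        # occasional ring closure
        if len(members) >= 4 and rng.random() < 0.3:
            existing = {bond.atoms for bond in b.bonds}
            u, v = rng.sample(members, 2)
            if (min(u, v), max(u, v)) not in existing:
                b.bond(u, v)
        species_atoms.append(members)
    # explicit hydrogens as leaves on random heavy atoms
    for _ in range(n_atoms - n_heavy):
        members = rng.choice(species_atoms)
        anchor = rng.choice(members)
        aid = b.add(next_id, H)
        next_id += 1
        b.bond(anchor, aid)
    return b.build()


def _random_arrow(
    rng: random.Random, state: ActiveSiteState, cfg: GeneratorConfig
) -> CurlyArrow | None:
    atom_ids = [a.atom_id for a in state.atoms]
    heavy_ids = [a.atom_id for a in state.atoms if a.element != H]
    bonds = list(state.bonds)
    for _ in range(60):
        if bonds and rng.random() < cfg.bond_source_fraction:
            src_bond = rng.choice(bonds)
            source = ArrowEndpoint.bond(*src_bond.atoms)
        else:
            source = ArrowEndpoint.atom(rng.choice(heavy_ids))
        sink_kind = rng.choices(("atom", "bond", "incipient"), weights=(3, 3, 4))[0]
        if sink_kind == "atom":
            cands = [a for a in atom_ids if ArrowEndpoint.atom(a) != source]
            sink = ArrowEndpoint.atom(rng.choice(cands))
        elif sink_kind == "bond":
            if not bonds:
                continue
            sb = rng.choice(bonds)
            sink = ArrowEndpoint.bond(*sb.atoms)
            if sink == source:
                continue
        else:
            # incipient bond growing out of the source, mimicking an attack
            root = rng.choice(source.atoms)
            blocked = set(state.adjacency[root]) | {root}
            cands = [a for a in atom_ids if a not in blocked]
            if not cands:
                continue
            sink = ArrowEndpoint.incipient(root, rng.choice(cands))
        arrow = CurlyArrow(2 if rng.random() < 0.95 else 1, source, sink)
        if len(reaction_centres(arrow)) <= 4:
            return arrow
    return None


def random_mechanism(
    config: GeneratorConfig, mechanism_id: str | None = None
) -> Mechanism:
    """Seeded-deterministic, validation-clean synthetic mechanism."""
    rng = random.Random(config.seed)
    n_steps = rng.randint(*config.n_steps)
    steps = []
    for idx in range(1, n_steps + 1):
        state = _random_state(rng, config)
        n_arrows = rng.randint(*config.arrows_per_step)
        arrows = []
        for _ in range(n_arrows):
            arrow = _random_arrow(rng, state, config)
            if arrow is None:
                raise GeneratorError(
                    "could not place an arrow; configuration too constrained"
                )
            arrows.append(arrow)
        steps.append(CatalyticStep(idx, state, tuple(arrows)))
    mech = Mechanism(
        mechanism_id or f"synthetic_{config.seed}",
        tuple(steps),
    )
    violations = validate_mechanism(mech)
    if violations:  # pragma: no cover - generator guarantees validity
        raise GeneratorError(f"generator produced an invalid mechanism: {violations}")
    return mech


def random_corpus(
    n: int, config: GeneratorConfig | None = None
) -> list[Mechanism]:
    """``n`` independent random mechanisms with derived per-mechanism seeds."""
    config = config or GeneratorConfig()
    out = []
    for i in range(n):
        sub = replace(config, seed=(config.seed * 1_000_003 + i) % (2**31))
        out.append(random_mechanism(sub, mechanism_id=f"synthetic_{i:04d}"))
    return out


# ---------------------------------------------------------------------------
# Mutation

_SWAP_TARGETS = (C, N, O, S, P, 9, 17)


def mutate_mechanism(mech: Mechanism, n_edits: int, seed: int) -> Mechanism:
    """Apply ``n_edits`` random validity-preserving edits.

    Edits are element swaps and formal-charge changes on atoms outside
    every arrow's reaction centres, plus occasional arrow-sink rewires.
    Edits for the same seed are drawn as one sequence, so a larger
    ``n_edits`` extends the smaller run.  ``n_edits=0`` is the identity.
    """
    if n_edits < 0:
        raise ValueError("n_edits must be >= 0")
    if n_edits == 0:
        return mech
    rng = random.Random(seed)
    steps = [
        {
            "atoms": {a.atom_id: a for a in s.state.atoms},
            "bonds": list(s.state.bonds),
            "arrows": list(s.arrows),
            "index": s.step_index,
        }
        for s in mech.steps
    ]
    edited: set[tuple[int, int]] = set()
    for _ in range(n_edits):
        kind = rng.choices(("element", "charge", "rewire"), weights=(6, 2, 2))[0]
        si = rng.randrange(len(steps))
        step = steps[si]
        if kind in ("element", "charge"):
            centres: set[int] = set()
            for arrow in step["arrows"]:
                centres |= reaction_centres(arrow)
            cands = [a for a in sorted(step["atoms"]) if a not in centres]
            fresh = [a for a in cands if (si, a) not in edited]
            if fresh:
                cands = fresh
            if not cands:
                continue
            aid = rng.choice(cands)
            edited.add((si, aid))
            atom = step["atoms"][aid]
            if kind == "element":
                choices = [z for z in _SWAP_TARGETS if z != atom.element]
                step["atoms"][aid] = replace(atom, element=rng.choice(choices))
            else:
                delta = rng.choice([-1, 1])
                step["atoms"][aid] = replace(
                    atom, formal_charge=atom.formal_charge + delta
                )
        else:
            ai = rng.randrange(len(step["arrows"]))
            arrow = step["arrows"][ai]
            state = ActiveSiteState(
                tuple(step["atoms"][k] for k in sorted(step["atoms"])),
                tuple(step["bonds"]),
            )
            new = None
            for _ in range(30):
                cand_sink_atom = rng.choice(sorted(step["atoms"]))
                sink = ArrowEndpoint.atom(cand_sink_atom)
                if sink == arrow.source or sink == arrow.sink:
                    continue
                trial = CurlyArrow(arrow.electrons, arrow.source, sink)
                if len(reaction_centres(trial)) <= 4:
                    new = trial
                    break
            if new is not None:
                step["arrows"][ai] = new
    new_steps = tuple(
        CatalyticStep(
            step["index"],
            ActiveSiteState(
                tuple(step["atoms"][k] for k in sorted(step["atoms"])),
                tuple(step["bonds"]),
            ),
            tuple(step["arrows"]),
        )
        for step in steps
    )
    mutated = Mechanism(mech.mechanism_id, new_steps, mech.annotations)
    violations = validate_mechanism(mutated)
    if violations:  # pragma: no cover - edits are validity-preserving
        raise GeneratorError(f"mutation broke validity: {violations}")
    return mutated
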