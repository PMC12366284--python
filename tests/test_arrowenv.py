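"""Arrow-env extraction, shells and canonical keys.

The canonical key is validated against an independent VF2 isomorphism
oracle (networkx) with the same label predicate, and against brute-force
BFS for shell membership.
"""

import random

import networkx as nx
import pytest

from mechsim import (
    ArrowEndpoint,
    EZMECHANISM_LIKE,
    GeneratorConfig,
    ONE_AWAY,
    TWO_AWAY,
    ArrowEnvDefinition,
    AtomNode,
    BondEdge,
    ActiveSiteState,
    CatalyticStep,
    CurlyArrow,
    EndpointKind,
    MechsimError,
    env_equal,
    extract_arrow_env,
    get_definition,
    random_corpus,
    random_mechanism,
    shell_atoms,
)
from mechsim.arrowenv import EnvAtom


def _env_to_nx(env):
    g = nx.Graph()
    for i, a in enumerate(env.atoms):
        g.add_node(i, label=a.label)
    idx = {a.atom_id: i for i, a in enumerate(env.atoms)}
    for b in env.bonds:
        g.add_edge(idx[b.atom_a], idx[b.atom_b], order=b.order.value)
    return g


def _vf2_isomorphic(env_a, env_b):
    """Independent oracle: label-preserving graph isomorphism via VF2."""
    return nx.is_isomorphic(
        _env_to_nx(env_a),
        _env_to_nx(env_b),
        node_match=lambda x, y: x["label"] == y["label"],
        edge_match=lambda x, y: x["order"] == y["order"],
    )


def _all_envs(mechs, definition):
    return [
        extract_arrow_env(step, arrow, definition)
        for mech in mechs
        for step in mech.steps
        for arrow in step.arrows
    ]


def _permuted_step(step, seed):
    """Same step with atom ids randomly relabelled."""
    rng = random.Random(seed)
    ids = [a.atom_id for a in step.state.atoms]
    new = ids[:]
    rng.shuffle(new)
    remap = dict(zip(ids, new))

    def ep(e):
        if e.kind is EndpointKind.BOND:
            return ArrowEndpoint.bond(*(remap[i] for i in e.atoms))
        return ArrowEndpoint(e.kind, tuple(remap[i] for i in e.atoms))

    return CatalyticStep(
        step.step_index,
        ActiveSiteState(
            tuple(AtomNode(remap[a.atom_id], a.element, a.formal_charge) for a in step.state.atoms),
            tuple(BondEdge(remap[b.atom_a], remap[b.atom_b], b.order) for b in step.state.bonds),
        ),
        tuple(CurlyArrow(a.electrons, ep(a.source), ep(a.sink)) for a in step.arrows),
    )


class TestShellAtoms:
    @pytest.fixture()
    def chain(self):
        atoms = tuple(AtomNode(i, 6) for i in range(1, 6))
        bonds = tuple(BondEdge(i, i + 1) for i in range(1, 5))
        return ActiveSiteState(atoms, bonds)

    def test_depth_one_on_linear_chain(self, chain):
        assert shell_atoms(chain, {3}, 1) == {2, 3, 4}

    def test_depth_zero_returns_centres(self, chain):
        assert shell_atoms(chain, {3}, 0) == {3}

    def test_unknown_centre_rejected(self, chain):
        with pytest.raises(MechsimError):
            shell_atoms(chain, {42}, 1)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("depth", [0, 1, 2, 3])
    def test_matches_brute_force_bfs(self, seed, depth):
        mech = random_mechanism(GeneratorConfig(seed=seed))
        state = mech.steps[0].state
        rng = random.Random(seed)
        ids = [a.atom_id for a in state.atoms]
        centres = set(rng.sample(ids, k=min(3, len(ids))))
        # oracle: networkx all-pairs shortest paths on the bond graph
        g = nx.Graph()
        g.add_nodes_from(ids)
        g.add_edges_from(b.atoms for b in state.bonds)
        expected = set()
        for c in centres:
            lengths = nx.single_source_shortest_path_length(g, c, cutoff=depth)
            expected |= set(lengths)
        assert shell_atoms(state, centres, depth) == expected


class TestExtraction:
    def test_fig1_one_away_env_shape(self, fig1_step):
        env = extract_arrow_env(fig1_step, fig1_step.arrows[0], ONE_AWAY)
        assert len(env.atoms) == 7
        assert len(env.bonds) == 5
        # mapped atoms are exactly the reaction centres
        assert env.mapped_atoms == {1, 10}

    def test_two_away_superset_of_one_away(self, fig1_step):
        for arrow in fig1_step.arrows:
            one = {a.atom_id for a in extract_arrow_env(fig1_step, arrow, ONE_AWAY).atoms}
            two = {a.atom_id for a in extract_arrow_env(fig1_step, arrow, TWO_AWAY).atoms}
            assert one < two

    def test_equivalence_classes_only_on_outermost_shell(self, fig1_step):
        for arrow in fig1_step.arrows:
            env = extract_arrow_env(fig1_step, arrow, EZMECHANISM_LIKE)
            two = extract_arrow_env(fig1_step, arrow, TWO_AWAY)
            outer = {a.atom_id for a in two.atoms} - shell_atoms(
                fig1_step.state, env.mapped_atoms, 1
            )
            for a in env.atoms:
                if a.equivalence is not None:
                    assert a.atom_id in outer
                    assert a.element in a.equivalence
                elif a.element in (1, 6):
                    assert a.atom_id not in outer

    def test_mapped_atoms_carry_electron_and_role_digits(self, fig1_step):
        env = extract_arrow_env(fig1_step, fig1_step.arrows[0], ONE_AWAY)
        digits = {a.atom_id: a.digits for a in env.atoms if a.digits}
        # nucleophile oxygen: tail (lone pair) and tip (incipient bond) -> both
        assert digits[1] == (2, 3)
        # attacked carbon: tip only
        assert digits[10] == (2, 2)

    def test_definition_requires_positive_depth(self):
        with pytest.raises(ValueError):
            ArrowEnvDefinition("bad", 0)

    def test_get_definition_unknown_name(self):
        with pytest.raises(KeyError):
            get_definition("three_away")


class TestCanonicalKey:
    def test_invariant_under_atom_id_permutation(self, small_corpus):
        for mech in small_corpus[:3]:
            for step in mech.steps:
                shuffled = _permuted_step(step, seed=step.step_index)
                for d in (ONE_AWAY, TWO_AWAY, EZMECHANISM_LIKE):
                    keys_a = sorted(
                        extract_arrow_env(step, a, d).canonical_key for a in step.arrows
                    )
                    keys_b = sorted(
                        extract_arrow_env(shuffled, a, d).canonical_key
                        for a in shuffled.arrows
                    )
                    assert keys_a == keys_b

    def test_charge_change_changes_key(self, fig1_step):
        env = extract_arrow_env(fig1_step, fig1_step.arrows[0], ONE_AWAY)
        atoms = list(env.atoms)
        atoms[0] = EnvAtom(
            atoms[0].atom_id, atoms[0].element, atoms[0].formal_charge - 1,
            atoms[0].equivalence, atoms[0].digits,
        )
        from mechsim.arrowenv import ArrowEnv

        other = ArrowEnv(tuple(atoms), env.bonds, env.definition)
        assert other.canonical_key != env.canonical_key

    def test_key_equality_iff_vf2_isomorphism(self, small_corpus):
        """Canonical-key equality must coincide with a label-preserving
        isomorphism found by an independent VF2 search."""
        envs = _all_envs(small_corpus[:4], ONE_AWAY)
        # guaranteed positives: each step re-extracted with permuted ids,
        # paired against its original
        pairs = []
        for mech in small_corpus[:2]:
            for step in mech.steps:
                perm = _permuted_step(step, seed=7)
                for orig, twin in zip(step.arrows, perm.arrows):
                    pairs.append(
                        (
                            extract_arrow_env(step, orig, ONE_AWAY),
                            extract_arrow_env(perm, twin, ONE_AWAY),
                        )
                    )
        rng = random.Random(1)
        while len(pairs) < 200:
            pairs.append((rng.choice(envs), rng.choice(envs)))
        n_equal = 0
        for a, b in pairs:
            same_key = a.canonical_key == b.canonical_key
            assert same_key == _vf2_isomorphic(a, b)
            n_equal += same_key
        assert 0 < n_equal < len(pairs)  # both outcomes exercised

    def test_cross_definition_comparison_rejected(self, fig1_step):
        a = extract_arrow_env(fig1_step, fig1_step.arrows[0], ONE_AWAY)
        b = extract_arrow_env(fig1_step, fig1_step.arrows[0], TWO_AWAY)
        with pytest.raises(MechsimError):
            env_equal(a, b)
        assert env_equal(a, a)


class TestCoarsening:
    def test_two_away_equality_implies_coarser_equality(self, small_corpus):
        """Equal two-away keys force equal one-away and EzMechanism-like
        keys: the coarser definitions only discard information."""
        mechs = list(small_corpus[:4])
        # duplicate one mechanism under permuted ids to guarantee positives
        arrows = [
            (step, arrow)
            for mech in mechs
            for step in mech.steps
            for arrow in step.arrows
        ]
        for step in mechs[0].steps:
            perm = _permuted_step(step, seed=3)
            arrows.extend((perm, a) for a in perm.arrows)
        keyed = [
            {
                d.name: extract_arrow_env(step, arrow, d).canonical_key
                for d in (ONE_AWAY, TWO_AWAY, EZMECHANISM_LIKE)
            }
            for step, arrow in arrows
        ]
        n_pos = 0
        for i in range(len(keyed)):
            for j in range(i + 1, len(keyed)):
                if keyed[i]["two_away"] == keyed[j]["two_away"]:
                    n_pos += 1
                    assert keyed[i]["one_away"] == keyed[j]["one_away"]
                    assert keyed[i]["ezmechanism_like"] == keyed[j]["ezmechanism_like"]
        assert n_pos > 0

    def test_fewer_distinct_ez_envs_than_two_away(self, small_corpus):
        ez = {e.canonical_key for e in _all_envs(small_corpus, EZMECHANISM_LIKE)}
        two = {e.canonical_key for e in _all_envs(small_corpus, TWO_AWAY)}
        assert len(ez) <= len(two)
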