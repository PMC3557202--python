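"""Single-run engine semantics: transition rules, asynchronous updates,
delayed reads, and agreement with the brute-force oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tridyn.dynamics import History, influence, simulate_run, step, update_node
from tridyn.network import Edge, NetworkSpec, Node

from conftest import make_chain, oracle_trajectory


class _FixedOrder:
    """Stand-in random stream yielding prescribed permutations."""

    def __init__(self, orders):
        self._orders = iter(orders)

    def permutation(self, n):
        order = next(self._orders)
        assert len(order) == n
        return np.array(order)


class TestUpdateNode:
    @pytest.mark.parametrize(
        "current, infl, expected",
        [
            # positive influence shifts up one level, saturating at 2
            (0, 1, 1), (1, 1, 2), (2, 1, 2), (1, 3, 2),
            # negative influence shifts down one level, saturating at 0
            (2, -1, 1), (1, -1, 0), (0, -1, 0), (1, -2, 0),
            # zero influence decays one level toward control
            (2, 0, 1), (0, 0, 1), (1, 0, 1),
        ],
    )
    def test_transition_table(self, current, infl, expected):
        assert update_node(current, infl) == expected


class TestInfluence:
    def _hist(self, net, init):
        return History(net, init)

    def test_single_activator_at_two(self):
        net = NetworkSpec(
            nodes=[Node("R", role="input", clamp_level=2), Node("T")],
            edges=[Edge("R", "T", "activate")],
        )
        assert influence("T", net, self._hist(net, {"R": 2, "T": 1})) == 1

    def test_activator_and_inhibitor_cancel(self):
        net = NetworkSpec(
            nodes=[
                Node("A", role="input", clamp_level=2),
                Node("I", role="input", clamp_level=2),
                Node("T"),
            ],
            edges=[Edge("A", "T", "activate"), Edge("I", "T", "inhibit")],
        )
        assert influence("T", net, self._hist(net, {"A": 2, "I": 2, "T": 1})) == 0

    def test_inhibitor_below_control_derepresses(self):
        net = NetworkSpec(
            nodes=[Node("I", role="input", clamp_level=0), Node("T")],
            edges=[Edge("I", "T", "inhibit")],
        )
        assert influence("T", net, self._hist(net, {"I": 0, "T": 1})) == 1

    def test_two_regulator_truth_table_matches_hand_enumeration(self):
        # signed-sum rule over one activator (state a) and one inhibitor
        # (state b): influence = (a-1) - (b-1)
        net = NetworkSpec(
            nodes=[Node("A"), Node("B"), Node("T")],
            edges=[Edge("A", "T", "activate"), Edge("B", "T", "inhibit")],
        )
        for a, b in itertools.product((0, 1, 2), repeat=2):
            hist = History(net, {"A": a, "B": b, "T": 1})
            assert influence("T", net, hist) == (a - 1) - (b - 1)

    def test_unregulated_node_has_zero_influence(self):
        net = NetworkSpec(nodes=[Node("X")], edges=[])
        assert influence("X", net, self._hist(net, {"X": 2})) == 0


class TestStep:
    def _chain(self):
        return NetworkSpec(
            nodes=[Node("A", role="input", clamp_level=2), Node("B"), Node("C")],
            edges=[Edge("A", "B", "activate"), Edge("B", "C", "activate")],
        )

    def test_downstream_order_realizes_immediately(self):
        net = self._chain()
        hist = History(net, {"A": 2, "B": 1, "C": 1})
        # ordinary order is [B, C]; permutation [0, 1] visits B then C
        step(net, hist, _FixedOrder([[0, 1]]))
        assert hist.state_at_lag("B", 0) == 2
        assert hist.state_at_lag("C", 0) == 2

    def test_upstream_order_sees_stale_state(self):
        net = self._chain()
        hist = History(net, {"A": 2, "B": 1, "C": 1})
        step(net, hist, _FixedOrder([[1, 0]]))  # C before B
        assert hist.state_at_lag("B", 0) == 2
        assert hist.state_at_lag("C", 0) == 1

    def test_all_clamped_network_step_is_identity(self):
        net = NetworkSpec(
            nodes=[Node("A", role="input", clamp_level=2),
                   Node("B", role="clamped", clamp_level=0)],
            edges=[Edge("A", "B", "activate")],
        )
        hist = History(net, {"A": 2, "B": 0})
        step(net, hist, _FixedOrder([[]]))
        assert hist.as_matrix().tolist() == [[2, 0], [2, 0]]


class TestSimulateRun:
    def test_horizon_one_equals_single_step(self, chain2):
        init = {"S": 2, "A": 1, "B": 1}
        traj = simulate_run(chain2, init, 1, np.random.default_rng(5))
        hist = History(chain2, init)
        step(chain2, hist, np.random.default_rng(5))
        assert np.array_equal(traj, hist.as_matrix())

    def test_horizon_must_be_positive(self, chain2):
        with pytest.raises(ValueError):
            simulate_run(chain2, {"S": 2, "A": 1, "B": 1}, 0, np.random.default_rng(0))

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_chain_terminal_reaches_two_by_row_k_for_every_order(self, k):
        # worst case is strictly upstream-last ordering; enumerate all
        # permutation sequences exhaustively
        net = make_chain(k)
        names = net.ordinary_nodes
        init = {"S": 2, **{n: 1 for n in names}}
        perms = list(itertools.permutations(range(k)))
        for seq in itertools.product(perms, repeat=k):
            traj = oracle_trajectory(
                net, init, [[names[i] for i in order] for order in seq]
            )
            assert traj[k][net.node_names.index(names[-1])] == 2

    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_delayed_target_stays_at_baseline_through_row_d(self, d):
        net = NetworkSpec(
            nodes=[Node("S", role="input", clamp_level=2), Node("T")],
            edges=[Edge("S", "T", "activate", delay=d)],
        )
        traj = simulate_run(net, {"S": 2, "T": 1}, d + 2, np.random.default_rng(0))
        t_col = net.node_names.index("T")
        assert all(traj[row, t_col] == 1 for row in range(d + 1))
        assert traj[d + 1, t_col] == 2

    def test_determinism_same_seed_bit_exact(self, chain_inhibit):
        init = {"S": 2, "A": 0, "B": 2}
        a = simulate_run(chain_inhibit, init, 20, np.random.default_rng(42))
        b = simulate_run(chain_inhibit, init, 20, np.random.default_rng(42))
        assert np.array_equal(a, b)


class TestInvariants:
    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), horizon=st.integers(1, 12))
    def test_states_bounded_and_clamped_columns_constant(self, seed, horizon):
        net = NetworkSpec(
            nodes=[
                Node("S", role="input", clamp_level=2),
                Node("K", role="clamped", clamp_level=0),
                Node("A"), Node("B"), Node("C"),
            ],
            edges=[
                Edge("S", "A", "activate"),
                Edge("A", "B", "activate", delay=1),
                Edge("K", "B", "inhibit"),
                Edge("B", "C", "inhibit"),
                Edge("C", "A", "inhibit"),
            ],
        )
        rng = np.random.default_rng(seed)
        traj = simulate_run(net, {"S": 2, "K": 0, "A": 1, "B": 1, "C": 1}, horizon, rng)
        assert np.isin(traj, (0, 1, 2)).all()
        assert (traj[:, net.node_names.index("S")] == 2).all()
        assert (traj[:, net.node_names.index("K")] == 0).all()

    @settings(max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_path_property(self, seed):
        # all-activator chain with active input: once a node hits 2 it
        # never drops below 1 while its regulator chain stays active
        net = make_chain(3)
        traj = simulate_run(
            net, {"S": 2, "N0": 1, "N1": 1, "N2": 1}, 15, np.random.default_rng(seed)
        )
        for name in ("N0", "N1", "N2"):
            col = traj[:, net.node_names.index(name)]
            first_two = np.argmax(col == 2) if (col == 2).any() else None
            if first_two is not None:
                assert (col[first_two:] >= 1).all()

    @pytest.mark.parametrize("delays", [[1, 1], [2, 1], [0, 3], [2, 2]])
    def test_delay_lower_bound_on_chains(self, delays):
        # total minimum path delay D: the terminal node cannot leave
        # baseline in rows 1..D
        net = make_chain(2, delays=delays)
        total = sum(delays)
        for seed in range(5):
            traj = simulate_run(
                net, {"S": 2, "N0": 1, "N1": 1}, total + 3, np.random.default_rng(seed)
            )
            col = traj[:, net.node_names.index("N1")]
            assert (col[: total + 1] == 1).all()

    def test_oracle_agreement_on_fixed_orders(self, chain_inhibit):
        # engine vs the independent dict-based interpreter, identical
        # forced update orders
        init = {"S": 2, "A": 1, "B": 2}
        orders = [["A", "B"], ["B", "A"], ["A", "B"]]
        idx = {n: i for i, n in enumerate(chain_inhibit.ordinary_nodes)}
        hist = History(chain_inhibit, init)
        for order in orders:
            step(chain_inhibit, hist, _FixedOrder([[idx[n] for n in order]]))
        expected = oracle_trajectory(chain_inhibit, init, orders)
        assert hist.as_matrix().tolist() == [list(r) for r in expected]
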