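"""State buffers, associative memories, ablation, and the two backends."""

import numpy as np
import pytest

from lexinaming import (
    AblationSpec,
    InputEvent,
    Network,
    SPVocabulary,
    Simulator,
    run_network,
)


@pytest.fixture
def vocab16():
    # 32-dimensional so that 16 random prototypes stay near-orthogonal
    v = SPVocabulary(32, seed=6)
    for i in range(8):
        v.create(f"in{i}")
    for i in range(8):
        v.create(f"out{i}")
    return v


def feedforward_net(seed=0):
    net = Network(seed=seed)
    net.add_buffer("x", 1, n_per=50)
    return net


class TestBufferDynamics:
    @pytest.mark.parametrize("backend", ["spiking", "direct"])
    def test_constant_input_decoded_within_tolerance(self, backend):
        net = feedforward_net()
        events = [InputEvent("x", np.array([0.5]), 0.0, 0.3)]
        _, out = run_network(net, events, 0.3, backend=backend, probes=["x"])
        t, vals = out["x"]
        # low-pass-filtered ideal: after 100 ms the filter has settled
        assert np.all(np.abs(vals[150:, 0] - 0.5) < 0.06)

    def test_zero_input_stays_near_zero(self):
        net = feedforward_net()
        _, out = run_network(net, [], 0.3, backend="spiking", probes=["x"])
        assert np.abs(out["x"][1]).max() < 0.1

    def test_recurrent_memory_retains_presented_pointer(self):
        v = SPVocabulary(16, seed=3)
        p = v.create("p")
        net = Network(seed=1)
        net.add_buffer("m", 16, recurrent=True, radius=1.0,
                       feedback=0.95, tau_feedback=0.1)
        events = [InputEvent("m", 0.4 * p.vector, 0.0, 0.3)]
        sim, out = run_network(net, events, 0.8, backend="spiking", probes=["m"])
        trace = sim.similarity_trace("m", *out["m"], v)
        s = trace.label_series("p")
        assert s[290] > 0.8  # loaded during presentation
        assert np.all(s[300:] > 0.7)  # held for a further 0.5 s
        # direct-mode integrator as oracle of the same contract
        sim2, out2 = run_network(net, events, 0.8, backend="direct", probes=["m"])
        s2 = sim2.similarity_trace("m", *out2["m"], v).label_series("p")
        assert np.all(s2[300:] > 0.7)

    def test_saturation_bounds_decoded_norm(self):
        v = SPVocabulary(16, seed=5)
        p = v.create("p")
        net = Network(seed=1)
        net.add_buffer("b", 16, radius=0.25)  # tight radius saturates
        events = [InputEvent("b", 3.0 * p.vector, 0.0, 0.3)]
        _, out = run_network(net, events, 0.3, backend="spiking", probes=["b"])
        assert np.linalg.norm(out["b"][1][-1]) < 1.5


def am_network(vocab16, wta=False, seed=1):
    ins = vocab16.matrix([f"in{i}" for i in range(8)])
    outs = vocab16.matrix([f"out{i}" for i in range(8)])
    net = Network(seed=seed)
    net.add_buffer("src", 32)
    net.add_buffer("dst", 32)
    net.add_assoc_memory("am", ins, outs, threshold=0.45, winner_take_all=wta,
                         inhibit=2.0 if wta else 0.0, ramp=0.55, fmax=1.0,
                         radius=1.2)
    net.connect("src", "am")
    net.connect("am", "dst")
    return net


class TestAssociativeMemory:
    @pytest.mark.parametrize("backend", ["direct", "spiking"])
    def test_prototype_maps_to_paired_output(self, vocab16, backend):
        net = am_network(vocab16)
        events = [InputEvent("src", vocab16["in2"].vector, 0.0, 0.4)]
        sim, out = run_network(net, events, 0.4, backend=backend, probes=["dst"])
        tr = sim.similarity_trace(
            "dst", *out["dst"], vocab16, [f"out{i}" for i in range(8)]
        )
        sims = tr.values[-1]
        assert sims[2] > 0.8
        assert np.delete(sims, 2).max() < 0.3

    def test_zero_input_gives_zero_output(self, vocab16):
        net = am_network(vocab16)
        sim, out = run_network(net, [], 0.3, backend="spiking", probes=["am"])
        assert np.abs(out["am"][1]).max() < 0.1

    def test_wta_passes_only_argmax_channel(self, vocab16):
        net = am_network(vocab16, wta=True)
        mix = 0.8 * vocab16["in2"].vector + 0.6 * vocab16["in5"].vector
        events = [InputEvent("src", mix, 0.0, 0.4)]
        sim, out = run_network(net, events, 0.4, backend="direct", probes=["am"])
        channels = out["am"][1][-1]
        oracle = int(np.argmax([vocab16[f"in{i}"].vector @ mix for i in range(8)]))
        assert int(np.argmax(channels)) == oracle == 2
        assert channels[5] < 0.1 * channels[2]

    def test_length_mismatch_rejected(self, vocab16):
        net = Network()
        with pytest.raises(ValueError, match="prototypes"):
            net.add_assoc_memory(
                "bad",
                vocab16.matrix(["in0", "in1"]),
                vocab16.matrix(["out0"]),
            )


class TestAblation:
    def make_sim(self, backend="spiking"):
        v = SPVocabulary(16, seed=4)
        p = v.create("p")
        net = Network(seed=2)
        net.add_buffer("b", 16, n_per=50)
        return v, p, net

    def test_fraction_zero_leaves_traces_identical(self):
        v, p, net = self.make_sim()
        events = [InputEvent("b", p.vector, 0.0, 0.2)]
        sim = Simulator(net, backend="spiking", seed=3)
        base = sim.run(0.2, events=events, probes=["b"])["b"][1].copy()
        sim2 = Simulator(net, backend="spiking", seed=3)
        sim2.ablate(AblationSpec("b", 0.0, seed=1))
        again = sim2.run(0.2, events=events, probes=["b"])["b"][1]
        assert np.array_equal(base, again)

    @pytest.mark.parametrize("backend", ["spiking", "direct"])
    def test_full_ablation_silences_output(self, backend):
        v, p, net = self.make_sim()
        events = [InputEvent("b", p.vector, 0.0, 0.2)]
        sim = Simulator(net, backend=backend, seed=3)
        sim.ablate(AblationSpec("b", 1.0, seed=1))
        out = sim.run(0.2, events=events, probes=["b"])
        assert np.abs(out["b"][1]).max() < 0.05

    def test_floor_rule_on_silenced_count(self):
        net = Network()
        net.add_buffer("b", 64, n_per=50)  # 3200 neurons
        sim = Simulator(net, backend="direct")
        sim.ablate(AblationSpec("b", 0.5, seed=0))
        assert (sim.mask == 0).sum() == 1600
        sim.clear_ablations()
        sim.ablate(AblationSpec("b", 0.333, seed=0))
        assert (sim.mask == 0).sum() == int(np.floor(0.333 * 3200))

    def test_unknown_target_rejected_with_valid_list(self):
        net = feedforward_net()
        sim = Simulator(net)
        with pytest.raises(KeyError, match="valid targets"):
            sim.ablate(AblationSpec("ghost", 0.5))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            AblationSpec("b", 1.5)

    @pytest.mark.parametrize("backend", ["spiking", "direct"])
    def test_mean_similarity_nonincreasing_with_fraction(self, backend):
        """Ablation is monotone in expectation across seeds."""
        v = SPVocabulary(16, seed=4)
        p = v.create("p")
        net = Network(seed=2)
        net.add_buffer("b", 16, n_per=50)
        events = [InputEvent("b", p.vector, 0.0, 0.2)]
        fractions = [0.0, 0.25, 0.5, 0.75, 1.0]
        means = []
        for frac in fractions:
            sims = []
            for seed in range(10):
                sim = Simulator(net, backend=backend, seed=3)
                sim.ablate(AblationSpec("b", frac, seed=seed))
                out = sim.run(0.2, events=events, probes=["b"])
                tr = sim.similarity_trace("b", *out["b"], v)
                sims.append(tr.label_series("p")[150:].mean())
            means.append(np.mean(sims))
        assert np.all(np.diff(means) <= 0.02)
        assert means[0] > 0.8 and abs(means[-1]) < 0.05


class TestEngineContracts:
    def test_unknown_input_target_rejected_before_simulation(self):
        net = feedforward_net()
        sim = Simulator(net)
        with pytest.raises(KeyError):
            sim.run(0.1, events=[InputEvent("ghost", np.array([1.0]), 0, 0.1)])

    def test_duration_shorter_than_step_rejected(self):
        sim = Simulator(feedforward_net())
        with pytest.raises(ValueError):
            sim.run(1e-5)

    def test_summary_reports_components_and_neuron_counts(self, vocab16):
        net = am_network(vocab16)
        s = net.summary()
        assert s["components"]["src"] == {"kind": "buffer", "n_neurons": 1600}
        assert s["components"]["am"]["kind"] == "assoc_memory"
        assert s["n_neurons"] == 1600 + 1600 + 8 * 50

    def test_same_seed_identical_runs(self, vocab16):
        net = am_network(vocab16)
        ev = [InputEvent("src", vocab16["in0"].vector, 0.0, 0.2)]
        a = Simulator(net, backend="spiking", seed=9).run(0.2, events=ev, probes=["dst"])
        b = Simulator(net, backend="spiking", seed=9).run(0.2, events=ev, probes=["dst"])
        assert np.array_equal(a["dst"][1], b["dst"][1])

    def test_trace_export_tidy_frame(self, vocab16):
        net = am_network(vocab16)
        ev = [InputEvent("src", vocab16["in0"].vector, 0.0, 0.2)]
        sim, out = run_network(net, ev, 0.2, backend="direct", probes=["dst"])
        tr = sim.similarity_trace("dst", *out["dst"], vocab16)
        df = tr.to_frame()
        assert set(df.columns) == {"time", "buffer", "label", "similarity"}
        assert len(df) == len(tr.time) * len(tr.labels)
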