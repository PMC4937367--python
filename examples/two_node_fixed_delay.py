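"""Detect a fixed-delay link between two binary channels.

Simulates the canonical two-node benchmark — cause Y and effect X both
firing spontaneously at probability 0.3, with each Y event inducing an X
event 4 samples later with probability 0.6 — then scans both directions
and prints the per-lag evidence.
"""

from cer import bidirectional_scan, make_delay, simulate_network, two_node_config

cfg = two_node_config(0.6, make_delay("fixed", tau=4), n=5000, seed=42)
sim = simulate_network(cfg)
scan = bidirectional_scan(sim.series["Y"], sim.series["X"], tau_max=10, alpha=0.005)

fwd = scan.forward
print(f"direction {fwd.direction[0]} -> {fwd.direction[1]}: "
      f"K_0 = {fwd.k0} zero-lag coincidences (the null reference)")
for lag, count, p in zip(fwd.lags, fwd.counts, fwd.pvalues):
    mark = " <-- significant" if lag in fwd.significant_lags else ""
    print(f"  lag {lag:2d}: K = {count:4d}  F(K|K_0) = {p:.4f}{mark}")
print(f"significant lags {set(fwd.significant_lags)} — the designed delay was 4")
print(f"reverse direction flags {len(scan.reverse.significant_lags)} lags "
      "(none expected: X does not cause Y)")
# A lag is flagged when its coincidence count is significantly above the
# zero-lag reference under the Poisson test: evidence that Y leads X there.
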