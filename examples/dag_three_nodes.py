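"""Pairwise direction inference on a three-node chain.

X drives Y and Y drives Z (discrete-Gaussian delays, non-stationary base
rates). Scanning each pair in both directions recovers every link's
orientation without conditioning on the third node: significant lags
appear only on the side where the true cause leads.
"""

from cer import (
    InteractionSpec,
    NodeSpec,
    RandomWalkSpec,
    SimulationConfig,
    bidirectional_scan,
    make_delay,
    simulate_network,
)

delay = make_delay(
    "gaussian-discrete", support=(2, 3, 4), probabilities=(0.225, 0.55, 0.225)
)
rw = RandomWalkSpec()
cfg = SimulationConfig(
    nodes=(NodeSpec("X", rw), NodeSpec("Y", rw), NodeSpec("Z", rw)),
    interactions=(
        InteractionSpec("X", "Y", 0.6, delay),
        InteractionSpec("Y", "Z", 0.6, delay),
    ),
    n=5000,
    seed=11,
)
sim = simulate_network(cfg)

for a, b in (("X", "Y"), ("Y", "Z"), ("X", "Z")):
    scan = bidirectional_scan(sim.series[a], sim.series[b], tau_max=10, alpha=0.005)
    print(f"{a} -> {b}: lags {sorted(scan.forward.significant_lags)} | "
          f"{b} -> {a}: lags {sorted(scan.reverse.significant_lags)}")
# X->Y and Y->Z show mass at the designed delays {2,3,4} with silent
# reverses. The indirect X->Z path is twice diluted (0.6 * 0.6 with
# compounded delays ~4..8) and usually stays below the threshold here,
# though pairwise scans can pick up strong ancestry, not just edges.
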