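"""How many catalytic sites exchange at once? Selection and the regime change.

Simulates a full exchange experiment (12 ATP concentrations, 10^5 Pi
molecules per condition), labels each condition with the best-fitting
site count n over {2, 3}, and locates the transition from three
exchanging sites (short times, high ATP) to two (long times, low ATP).
"""

from oxex import SimulationConfig, detect_transition, simulate_dataset
from oxex.simulate import DEFAULT_INITIAL

dataset = simulate_dataset(
    SimulationConfig(seed=11, molecules_per_condition=100_000)
)
result = detect_transition(
    dataset.observations, k=10.5, initial=DEFAULT_INITIAL
)

print("ATP (uM)   time 1/v (s)   true n   selected n")
ordered = sorted(dataset.records, key=lambda r: r.t_hydrolysis)
for record, n_hat in zip(ordered, result.labels):
    print(
        f"{record.observation.atp_conc:8.2f} {record.t_hydrolysis:13.4f}"
        f" {record.n_true:8d} {n_hat:12d}"
    )

print()
if result.found:
    lo, hi = result.bracket_times
    print(f"transition time ~ {1000 * result.transition_time:.1f} ms "
          f"(bracketed by {1000 * lo:.1f} and {1000 * hi:.1f} ms;")
    print(f"ATP bracket {result.bracket_atp[0]:.2f} to "
          f"{result.bracket_atp[1]:.2f} uM)")
    print("One catalytic site drops out of the exchange once the catalytic")
    print("cycle outlasts ~33 ms, i.e. between roughly 3 and 5 uM ATP.")
else:
    print("no transition detected in this series")
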