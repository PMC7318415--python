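"""Maximum feasible body-weight support per unloading strategy.

Sweeps BWS levels from 0 to 100 % in 5 % increments for the SLIP model;
a level is feasible when the walker completes 20 steps.  The highest
feasible level (beta_max) summarises how much unloading each strategy
tolerates before the gait breaks down.
"""

from bwsim import SLIPParams, find_beta_max

params = SLIPParams()
for strategy in ("cf", "cw", "ts"):
    sweep = find_beta_max("slip", params, strategy, init_value=1.1185)
    feasible = [lvl for lvl, r in sweep.per_level.items() if r.feasible]
    print(f"{strategy.upper()}: beta_max = {sweep.beta_max}%  "
          f"(feasible {min(feasible)}-{max(feasible)}%)")
# The counterweight fails earliest: its inertia perturbs the vertical
# dynamics most.  The tuned spring trades some feasibility range for
# preserving the gait's dynamics (see 03_similarity_metrics.py).
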