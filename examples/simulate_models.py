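"""Simulate the four learning models across the three practice-consistency conditions.

Builds one target schedule per condition (baseline 250 / learning 500 /
washout 750 strides), runs each model's noiseless dynamics, and prints the
washout aftereffect measures. Initial bias (mean SAI, washout strides 1-5)
is the total magnitude of use-dependent learning; early washout is strides
6-30.
"""

from stridelearn import make_schedule, simulate
from stridelearn.behavior import washout_epochs
from stridelearn.synthetic import DEFAULT_PARAMS

schedules = {cond: make_schedule(cond, seed=42) for cond in ("constant", "LV", "HV")}

print(f"{'model':<8} {'condition':<10} {'initial bias':>12} {'early washout':>14}")
for model in ("su", "ab", "mod_su", "mod_ab"):
    for cond, sched in schedules.items():
        x = simulate(model, DEFAULT_PARAMS[model], sched)
        ib, ew = washout_epochs(x, sched)
        print(f"{model:<8} {cond:<10} {ib:>12.2f} {ew:>14.2f}")
    print()

print(
    "Units are %SAI. The Adaptive Bayesian (ab) aftereffect decays within a\n"
    "few strides and shrinks as practice gets more variable, while the\n"
    "Strategy+Use-Dependent (su) bias is small but sustained; the modified\n"
    "S+U model (mod_su) combines a consistency-ordered initial bias\n"
    "(constant > LV > HV) with slow decay."
)
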