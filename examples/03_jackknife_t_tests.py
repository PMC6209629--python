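"""Test a latency difference with classical and jackknife-corrected t-tests.

Two conditions differ by a true 50 ms shift of a broad component.  The
contrast is tested three ways: a classical paired t on individual area
latencies, the corrected t on jackknife (leave-one-out) estimates, and a
classical t on Smulders-retrieved individual scores.
"""

from erplatency import (
    ComponentSpec,
    ConditionSpec,
    LatencyConfig,
    aggregate_extract,
    generate_group,
    jackknife_paired_t,
    paired_t,
)

groups, _ = generate_group(
    n_subjects=16,
    components=[ComponentSpec("gaussian", center=0.55, width=0.10, amplitude=6.0)],
    conditions={"intact": ConditionSpec(0.050), "scrambled": ConditionSpec(0.0)},
    noise_sd=3.0,
    jitter_sd=0.04,
    sfreq=500.0,
    seed=3,
)

base = dict(sign=1, extract=["areaLat"], peak_win=(0.35, 1.0))
est = {}
for mode in ("individual", "jackMiller", "jackSmulders"):
    est[mode] = {
        cond: aggregate_extract(g, LatencyConfig(aggregate=mode, **base))[0]
        for cond, g in groups.items()
    }

t_ind = paired_t(
    est["individual"]["intact"].values["areaLat"],
    est["individual"]["scrambled"].values["areaLat"],
)
t_jack = jackknife_paired_t(
    est["jackMiller"]["intact"].jack("areaLat"),
    est["jackMiller"]["scrambled"].jack("areaLat"),
)
t_smu = paired_t(
    est["jackSmulders"]["intact"].values["areaLat"],
    est["jackSmulders"]["scrambled"].values["areaLat"],
)

print("50%-area latency, intact vs. scrambled (true difference: 50 ms)")
print(f"  individual estimates : {t_ind.report(scale=1e3)}")
print(f"  jackknife, corrected : {t_jack.report(scale=1e3)}")
print(f"  Smulders retrieval   : {t_smu.report(scale=1e3)}")
print(
    "\nAll three routes agree on the ~50 ms effect. The t values are large "
    "because the generator applies the same per-subject jitter to both "
    "conditions (a pure within-subject design), so only extraction noise "
    "enters the paired differences. The jackknife routes matter in practice "
    "when individual averages are too noisy for stable per-subject latencies."
)
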