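"""How many subsamples, replicates and scans does a lot need?

Runs the resampling study on one lot: draw n scans under constraint
levels A (one subsample, tubes balanced) through E (free draw over all
subsamples), recompute the nested ANOVA each time, and watch the spread
of the MSQ summary shrink as n grows.  Levels restricted to a single
subsample plateau below the lot's overall variability: no number of
scans compensates for unsampled subsamples.
"""

from woodvar import ResamplingSpec, generate_dataset, msc, overall_variability, recommend_design, resample_msq
from woodvar.sampling import level_pool_size
from woodvar.simulate import SimulationConfig

cfg = SimulationConfig(n_lots=1, n_scans_per_replicate=120, seed=5)
lot, _, _ = generate_dataset(cfg)
lot, _ = msc(lot)

reference = overall_variability(lot)
print(f"overall variability of the lot (total mean square): {reference:.3e}\n")

results = {}
for i, level in enumerate("ABCDE"):
    spec = ResamplingSpec(level=level, repetitions=50, seed=100 + i)
    spec.n_grid = [n for n in spec.n_grid if n <= level_pool_size(lot, level)]
    results[level] = resample_msq(lot, spec)
    sp = results[level].spread
    print(f"level {level}: spread (sd over repetitions) "
          f"{sp['sd'].iloc[0]:.2e} at n={sp['n'].iloc[0]} -> "
          f"{sp['sd'].iloc[-1]:.2e} at n={sp['n'].iloc[-1]}; "
          f"plateau mean {sp['mean'].iloc[-1]:.3e}")

rec = recommend_design(results)
print(f"\nrecommended: level {rec['recommended_level']} with n = {rec['recommended_n']} scans")
for level, r in rec["per_level"].items():
    note = "below reference!" if r["undershoots_reference"] else "reaches reference"
    print(f"  level {level}: smallest stable n = {r['n']:4d}  ({note})")
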