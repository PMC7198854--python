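"""Compare the full method against its two ablations.

``full`` uses the degree-biased transition matrix and the seed-centrality
restart prior; ``uniform_transition`` (RW_UniTr) spreads each step equally
over out-neighbors; ``no_seeds`` (IRW_withoutS) restarts uniformly at 1/n.
All three share the mutation post-filter and the top-N evaluation.
"""

from driver_irw import FixtureConfig, make_inputs, run_ablation

cfg = FixtureConfig(rng_seed=0)
inputs, benchmark = make_inputs(cfg)

print("mode                top-30 precision   top-30 recall")
for mode in ("full", "uniform_transition", "no_seeds"):
    ranked, curve = run_ablation(inputs, benchmark, mode=mode, n_max=30)
    prec, rec = curve.at(min(30, len(ranked)))
    print(f"{mode:<20}{prec:>14.3f}{rec:>16.3f}")

print("\nHigher is better; any gap between 'full' and the ablations is the")
print("contribution of the degree-biased transition and the seed prior. On the")
print("default fixture the planted signal is strong enough that all three modes")
print("saturate at the top-30 — the ablations matter on weaker, noisier inputs.")
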