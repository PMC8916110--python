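"""Does cortical thickness mediate the age -> connectivity decline?

Parallel-mediator model: age -> {cortical thickness, PSMD} -> subnetwork
FC.  Indirect effects are products a_j * b_j; inference is by case
resampling (10,000 bootstrap draws, percentile CIs).  The generator plants
a genuine thickness channel, so thickness should mediate and PSMD should
not.
"""

from fcaging import (
    GeneratorConfig,
    MediationModel,
    bootstrap_mediation,
    generate_cohort,
    generate_connectomes,
    subnetwork_fc,
)

config = GeneratorConfig(n_subjects=976, n_rois=100, seed=5)
cohort = generate_cohort(config)
stack, truth = generate_connectomes(config, cohort)
cohort["subnet_fc"] = subnetwork_fc(stack, list(truth.planted_edges))

model = MediationModel(
    exposure="age", mediators=("cortical_thickness", "psmd"), outcome="subnet_fc"
)
res = bootstrap_mediation(cohort, model, n_boot=10_000, seed=0)

print(res.to_frame().to_string(index=False, float_format=lambda v: f"{v:+.5f}"))
print()
ind = res.effects["indirect_cortical_thickness"]
print(
    f"thickness indirect effect {ind.estimate:+.5f} "
    f"[{ind.ci_low:+.5f}, {ind.ci_high:+.5f}], p = {ind.p:.4f}"
)
print(f"true planted indirect (a*b) = {truth.true_paths['a'] * truth.true_paths['b']:+.5f}")
print()
print("The thickness CI excludes zero (partial mediation); the PSMD CI")
print("does not, because PSMD enters no edge equation in the generator.")
print(f"Decomposition: total = direct + indirect holds exactly "
      f"({res.total:+.5f} = {res.direct:+.5f} + "
      f"{res.effects['indirect_sum'].estimate:+.5f}).")
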