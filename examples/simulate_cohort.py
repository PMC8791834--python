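"""Generate a synthetic multi-omic neoadjuvant cohort and inspect its shape.

The generator draws latent patient traits (mutation burden, HRD,
proliferation, immune infiltration, ...), maps them to a latent response
score, bins the score into ordered residual-cancer-burden (RCB) classes, and
emits every data table the downstream feature extractors consume.
"""

from neoresponse import SimulationConfig, simulate_cohort

cfg = SimulationConfig(n_patients=100, seed=7)
bundle = simulate_cohort(cfg)

print("patients:", len(bundle.clinical))
print("RCB distribution:",
      bundle.clinical["rcb_class"].value_counts().to_dict())
print("somatic mutations:", len(bundle.mutations))
print("copy-number segments:", len(bundle.segments))
print("expression matrix:", bundle.expression.shape, "(genes x patients)")
print("classified cells:", len(bundle.cells))
print("neoepitope candidates:", len(bundle.affinities))

# The ground truth records what was planted, e.g. the latent response and the
# per-mutation cancer cell fractions, so every extractor can be checked.
gt = bundle.ground_truth
print("latent response mean/sd: "
      f"{gt.latent.mean():.2f} / {gt.latent.std():.2f}")
print("pCR fraction:", round((gt.rcb_class == 'pCR').mean(), 3))
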