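"""Generate a synthetic drug-target interaction dataset and inspect it.

The generator emulates curated DTI benchmarks: a low-rank latent interaction
term, per-entity activity biases, and assortative observation (screened pairs
mostly connect entities whose overall activity agrees).  The printed
polarization is the fraction of entities whose observed labels are all
identical - high polarization is what lets entity-wise cross-validation leak.
"""

from erfusion import SyntheticSpec, generate_dti, polarization_report

spec = SyntheticSpec()  # 300 drugs x 250 proteins, 2000 observed cells
ds = generate_dti(spec, seed=7)

pol = polarization_report(ds.cells, ds.values)
print(f"observed cells:       {len(ds.cells)}")
print(f"positive fraction:    {ds.values.mean():.3f}")
print(f"drug polarization:    {pol.drug_fraction:.3f}")
print(f"protein polarization: {pol.protein_fraction:.3f}")
print(f"combined:             {pol.combined:.3f}")
print("A combined polarization near 0.94 reproduces the regime of curated")
print("human DTI data, where almost every entity is only-active or only-inactive.")
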