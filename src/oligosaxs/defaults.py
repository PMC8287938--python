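"""Central table of default analysis constants.

Every tunable the pipeline relies on lives here so a run report can
record the full resolved parameter set.
"""

DEFAULTS: dict = {
    # Guinier
    "srg_limit": 1.3,        # validity limit s_max·Rg of the Guinier window
    "r2_min": 0.99,          # minimum weighted r² of the Guinier fit
    "min_points": 5,         # minimum points in a Guinier window
    "max_first_skip": 5,     # leading points skippable (beamstop artifacts)
    # reduction
    "n_peak_frames": 20,     # frames averaged at the chromatogram peak
    "buffer_margin": 5,      # frames between buffer window and peak onset
    # Kratky / flexibility
    "flex_threshold": 0.5,   # high-angle Kratky mean flagging flexibility
    # P(r) / Porod
    "n_bins": 100,           # P(r) grid points
    "alpha": None,           # regularization weight (None = L-curve)
    "nonneg": True,          # enforce P(r) >= 0
    "s_cut": 0.25,           # Å⁻¹, Porod integration cutoff
    "porod_background": True,  # subtract residual constant background
    # mass / oligomer
    "porod_divisor": 1.66,   # Å³ per Da
    "oligomer_delta_frac": 0.10,  # relative MW uncertainty for n-mer range
    # geometry
    "probe_radius": 1.4,     # Å, solvent probe
    "sasa_points": 960,      # Shrake–Rupley sphere points
    "dsasa_min": 0.1,        # Å², interface-residue threshold
    "contact_cutoff": 4.5,   # Å, hydrophobic C–C contact cutoff
}
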