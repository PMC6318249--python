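"""Hard-sphere theoretical CCS and experiment-vs-theory contraction.

Validates the two Monte-Carlo engines on a single sphere (where both
must equal the analytic disk area), shows EHSS exceeding PA on a
concave body, and computes the percent contraction of an experimental
CCS below a theoretical value — the metric used to quantify gas-phase
structural collapse after desolvation.
"""

import numpy as np

import nativeimms as ni

# single atom: PA = EHSS = pi (r + r_gas)^2
atom = ni.generate_toy_structure("sphere-shell", 1, atom_radius=1.7)
pa = ni.pa_ccs(atom, gas_radius=1.0, seed=1)
eh = ni.ehss_ccs(atom, gas_radius=1.0, n_trajectories=50_000, seed=1)
analytic = np.pi * 2.7 ** 2 / 100.0
print(f"single sphere: analytic {analytic:.4f} nm^2, "
      f"PA {pa.value:.4f} +/- {pa.mc_standard_error:.4f}, "
      f"EHSS {eh.value:.4f} +/- {eh.mc_standard_error:.4f}")

# a random concave cluster: multiple scattering makes EHSS > PA
rng = np.random.default_rng(3)
cluster = ni.AtomicStructure(["C"] * 50, rng.uniform(-8, 8, size=(50, 3)))
pa_c = ni.pa_ccs(cluster, seed=2)
eh_c = ni.ehss_ccs(cluster, n_trajectories=50_000, seed=2)
print(f"concave cluster: PA {pa_c.value:.3f} nm^2, EHSS {eh_c.value:.3f} "
      f"nm^2 (EHSS/PA = {eh_c.value / pa_c.value:.2f})")

# experiment vs theory: a measured 57.5 nm^2 against an EHSS 62.5 nm^2
contraction = ni.contraction_percent(ccs_exp=57.5, ccs_theory=62.5)
print(f"contraction of experiment below theory: {contraction:.1f} %")
# Positive contraction means the gas-phase ion is more compact than the
# model structure, e.g. through collapse of an internal cavity during
# electrospray desolvation.
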