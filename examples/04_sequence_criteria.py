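"""Sequence descriptors and probe-validity criteria.

For a set of model polyampholyte sequences: the charge-patterning
descriptor nSCD (0 = perfectly alternating, 1 = diblock), the dense-
phase correlation length from chain dimensions, and the two criteria a
probe must satisfy for continuum microrheology: size (R_h/ξ ≥ 1.5) and
interaction strength (1 ≤ ε/ε_HPS ≤ 1.5).
"""

from microrheo import hps

sequences = {
    "alternating (EK)25": "EK" * 25,
    "blocky (E5K5)5": ("E" * 5 + "K" * 5) * 5,
    "diblock E25K25": "E" * 25 + "K" * 25,
}
for name, seq in sequences.items():
    print(f"nSCD[{name}] = {hps.nscd(seq):.3f}")

# dense phase of a 50-mer: end-to-end distance 40 Å, chain mass
# 6407 g/mol, density twice the overlap concentration
res = hps.correlation_length(rho=2 * 3 * 6407.0 / (4 * 3.141592653589793
                                                   * 40.0 ** 3),
                             Re=40.0, Mw=6407.0)
print(f"\ncorrelation length xi = {res.xi:.1f} Å "
      f"(overlap concentration {res.rho_star:.2e} g/(mol·Å³))")

for rh in (6.2, 10.6, 16.0):
    v = hps.probe_size_criterion(rh, 7.0)
    print(f"R_h = {rh:5.1f} Å, xi = 7 Å: R_h/xi = {v['ratio']:.2f} -> "
          f"{v['verdict']}{'  (' + v['note'] + ')' if v['note'] else ''}")

for eps in (0.5, 1.0, 2.0):
    print(f"eps/eps_HPS = {eps}: "
          f"{hps.interaction_window_check(eps)['verdict']}")

# pair energies at contact-ish separations
print(f"\nE-K electrostatics at 10 Å: "
      f"{hps.coulomb_energy(10.0, -1, +1):.4f} kcal/mol")
print(f"hydrophobic contact (λ=1) at the LJ minimum: "
      f"{hps.vdw_energy(2 ** (1 / 6) * 6.0, 1.0, 1.0, 6.0, 6.0):.3f} "
      "kcal/mol")
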