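# Default model parameters for the pancreas-liver chip digital twin.
#
# Units: time h, volumes L, glucose mmol (concentrations mmol/L),
# insulin mIU (concentrations mIU/L).
#
# Geometry and operation reflect the chip: 300 ul medium per
# compartment, 15 ul pooled GTT draws, mean flow 4.94 ul/min.
# The kinetic values (E_G0, S_I0, I_max_Si, EC50_Si, sigma_max, alpha,
# EC50_I, k_elimination, k_v, d_0, r1, r2, tau_slow) are ASSUMPTIONS
# chosen to give realistic 15-day dynamics (glucose load cleared below
# normoglycemia within 48 h, insulin in the tens of mIU/L, ~20%
# beta-cell loss under sustained hyperglycemia); every value can be
# overridden.
hypothesis: H1
geometry.V_m_liver: 3.0e-4
geometry.V_m_pancreas: 3.0e-4
geometry.V_HepaRG_spheroids: 3.0e-6
geometry.Q: 2.964e-4            # 4.94 ul/min in L/h
geometry.V_sample_liver: 1.5e-5
geometry.V_sample_pancreas: 1.5e-5
fast.E_G0: 1.0                  # 1/h, insulin-independent disposal
fast.S_I0: 0.033                # L/mIU/h, initial insulin sensitivity
fast.I_max_Si: 0.85             # max fractional S_I loss from hyperglycemia
fast.EC50_Si: 150.0             # mmol*h/L, half-max excess-glucose integral
fast.EGP: 0.0                   # mmol/L/h, endogenous glucose production
fast.sigma_max: 2.0e6           # mIU/L/h per L beta cells
fast.alpha: 22500.0             # h^2 (half capacity at 150 h)
fast.EC50_I: 7.0                # mmol/L, half-max glucose for secretion
fast.k_elimination_I_spheroids: 5.0   # 1/h
fast.G_normo: 5.5               # mmol/L
slow.k_v: 1.0
slow.d_0: 2.5e-3                # 1/h, death rate at zero glucose
slow.r1: 1.0e-3                 # L/mmol/h
slow.r2: 9.0e-5                 # L^2/mmol^2/h
slow.tau_slow: 24.0             # h
slow.V_beta_0: 8.8e-9           # L
offsets.dG_d1: 0.0
offsets.dG_d13: 0.0
offsets.dI_d1: 0.0
offsets.dI_d13: 0.0
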