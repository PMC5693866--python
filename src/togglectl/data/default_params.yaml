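# Fitted kinetic and regulatory parameters of the reference toggle switch.
# Units: rates per minute; protein/mRNA thresholds in a.u.; theta_aTc in
# ng/mL; theta_IPTG in mM; Hill exponents dimensionless.
k_m0_L: 3.20e-2
k_m0_T: 1.19e-1
k_m_L: 8.30
k_m_T: 2.06
k_p_L: 9.726e-1
k_p_T: 1.170
g_m_L: 1.386e-1
g_m_T: 1.386e-1
g_p_L: 1.65e-2
g_p_T: 1.65e-2
theta_LacI: 31.94
theta_TetR: 30.00
theta_aTc: 11.65
theta_IPTG: 9.06e-2
eta_LacI: 2.0
eta_TetR: 2.0
eta_aTc: 2.0
eta_IPTG: 2.0
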