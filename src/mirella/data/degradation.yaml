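# Default parameterisation of the finite-RNase (degradation) model.
# Units: concentrations nM, time h; association constants in nM^-1 h^-1.
# Calibrated so the endogenous transcript has an hours-scale half-life
# (~2.3 h at eta_plus = 0), basal complexes turn over fast (low RNase
# occupancy in the control) while miRNA-committed complexes occupy the
# machinery (association boosted 10x, completion slower), placing the
# biphasic-decay onset near eta_plus ~ 2 nM^-1 h^-1.
model: degradation
n_T: 1.0            # miTarget gene copies
n_E: 1.0            # endogenous gene copies
alpha_T: 40.0       # nM/h per copy, miTarget transcription
alpha_E: 20.0       # nM/h per copy, endogenous transcription
alpha_Q: 0.1        # nM/h, miRNA production (free miRNA ~0.5 nM)
beta_Q: 0.2         # 1/h, miRNA decay
eta_plus: 0.0       # nM^-1 h^-1, miRNA binding (0 = control)
eta_minus: 1.0      # 1/h, complex dissociation
betaT_assoc: 0.02   # nM^-1 h^-1, basal miTarget-RNase association
betaTQ_assoc: 0.2   # nM^-1 h^-1, miRNA-boosted association
betaE_assoc: 0.0055 # nM^-1 h^-1, endogenous-RNase association
betaT_dissoc: 1.0   # 1/h, miTarget:RNase dissociation
betaE_dissoc: 1.0   # 1/h, endogenous:RNase dissociation
betaT_cat: 20.0     # 1/h, completion of basal miTarget complexes
betaTQ_cat: 0.8     # 1/h, completion of miRNA-committed complexes
betaE_cat: 20.0     # 1/h, completion of endogenous complexes
z_total: 60.0       # nM, total RNase pool
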