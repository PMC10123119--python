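# Default parameterisation of the ribosome-competition (translation) model.
# Units: concentrations nM, time h; eta_plus in nM^-1 h^-1.
# Chosen so that baseline ribosome demand is rho_T = rho_C = 5 (total ~10),
# mRNA half-lives are hours-scale and protein dilution ~ cell division.
model: translation
n_T: 1.0          # miTarget gene copies
n_C: 1.0          # capacity monitor gene copies
alpha_T: 10.0     # nM/h per copy, miTarget transcription
alpha_C: 10.0     # nM/h per copy, monitor transcription
alpha_Q: 0.0015   # nM/h, miRNA production (free miRNA ~0.003 nM)
beta_T: 0.2       # 1/h, basal miTarget mRNA decay (t1/2 ~ 3.5 h)
beta_C: 0.2       # 1/h, monitor mRNA decay
beta_Q: 0.5       # 1/h, miRNA decay
lambda_TQ: 10.0   # fold-increase of miRNA-enhanced decay (beta_TQ = 2 /h)
gamma_T: 10.0     # 1/h, translation rate
gamma_C: 10.0     # 1/h
delta_T: 0.1      # 1/h, protein dilution (t1/2 ~ 7 h)
delta_C: 0.1      # 1/h
kappa_T: 10.0     # nM, effective ribosome-mRNA dissociation
kappa_C: 10.0     # nM
eta_plus: 0.0     # nM^-1 h^-1, miRNA binding (0 = no-miRNA control)
eta_minus: 1.0    # 1/h, complex dissociation
sigma: 1          # TS location: 0 = 5'UTR, 1 = 3'UTR
r_total: 1000.0   # nM, total ribosome pool
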