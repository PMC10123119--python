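"""Closed-form steady-state analysis of the ribosome-competition model.

The steady state of the translation model admits an exact solution in
terms of three dimensionless *resource demand coefficients* — the load
each transcript pool places on the shared ribosome pool:

    rho_T  = n_T alpha_T / (kappa_T (beta_T + alpha_Q eta+ beta_TQ /
                                     (beta_Q (beta_TQ + eta-))))
    rho_TQ = n_T alpha_T / (kappa_T (beta_TQ + beta_T beta_Q (beta_TQ + eta-) /
                                     (alpha_Q eta+)))
    rho_C  = n_C alpha_C / (kappa_C beta_C)

and the steady-state proteins follow a shared-resource partition:

    p_T = (gamma_T/delta_T) (rho_T + sigma rho_TQ) / D * r_total
    p_C = (gamma_C/delta_C) rho_C / D * r_total,   D = 1 + rho_T + sigma rho_TQ + rho_C

with free ribosomes r = r_total / D. The demand coefficients double as
steady-state mRNA levels: m_T = rho_T kappa_T, m_Q = rho_TQ kappa_T.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .parameters import TranslationParams


@dataclass(frozen=True)
class DemandCoefficients:
    """Dimensionless ribosome demand of each transcript pool."""

    rho_T: float   # free miTarget mRNA
    rho_TQ: float  # miTarget:miRNA complex
    rho_C: float   # capacity monitor mRNA

    @property
    def total_miTarget(self) -> float:
        """Combined demand of all miTarget-derived transcripts."""
        return self.rho_T + self.rho_TQ


@dataclass(frozen=True)
class SteadyStateSummary:
    """Steady state of the translation model (concentrations in nM)."""

    p_T_bar: float      # miTarget protein
    p_C_bar: float      # capacity monitor protein
    r_bar: float        # free ribosomes
    density_T: float    # translating ribosomes per miTarget transcript
    density_C: float    # translating ribosomes per monitor transcript
    m_T_bar: float      # free miTarget mRNA
    m_Q_bar: float      # miTarget:miRNA complex
    m_C_bar: float      # monitor mRNA
    q_bar: float        # free miRNA

    def as_dict(self) -> dict:
        return asdict(self)


def demand_coefficients(params: TranslationParams) -> DemandCoefficients:
    """Resource demand coefficients of the translation model.

    At eta_plus = 0 the miRNA-bound pool vanishes and rho_TQ is taken as
    its (zero) limit rather than a division error.
    """
    p = params
    beta_TQ = p.beta_TQ
    if p.eta_plus > 0:
        mi_flux = p.alpha_Q * p.eta_plus / (p.beta_Q * (beta_TQ + p.eta_minus))
        rho_T = p.n_T * p.alpha_T / (p.kappa_T * (p.beta_T + mi_flux * beta_TQ))
        rho_TQ = p.n_T * p.alpha_T / (p.kappa_T * (beta_TQ + p.beta_T / mi_flux))
    else:
        rho_T = p.n_T * p.alpha_T / (p.kappa_T * p.beta_T)
        rho_TQ = 0.0
    rho_C = p.n_C * p.alpha_C / (p.kappa_C * p.beta_C)
    return DemandCoefficients(rho_T=rho_T, rho_TQ=rho_TQ, rho_C=rho_C)


def steady_state(params: TranslationParams) -> SteadyStateSummary:
    """Exact steady state of the translation model.

    Ribosomal density is the number of translating ribosomes per total
    transcript of a gene; for the miTarget the average runs over free
    *and* miRNA-bound transcripts, only the sigma-gated fraction of which
    carries ribosomes.
    """
    p = params
    rho = demand_coefficients(p)
    denom = 1.0 + rho.rho_T + p.sigma * rho.rho_TQ + rho.rho_C
    r_bar = p.r_total / denom
    p_T_bar = (p.gamma_T / p.delta_T) * (rho.rho_T + p.sigma * rho.rho_TQ) / denom * p.r_total
    p_C_bar = (p.gamma_C / p.delta_C) * rho.rho_C / denom * p.r_total

    m_T_bar = rho.rho_T * p.kappa_T
    m_Q_bar = rho.rho_TQ * p.kappa_T
    m_C_bar = p.n_C * p.alpha_C / p.beta_C
    q_bar = p.alpha_Q / p.beta_Q

    density_C = r_bar / p.kappa_C
    total_T = m_T_bar + m_Q_bar
    # bound ribosomes on miTarget transcripts / total miTarget transcripts
    density_T = r_bar * (m_T_bar + p.sigma * m_Q_bar) / (p.kappa_T * total_T)
    return SteadyStateSummary(
        p_T_bar=p_T_bar,
        p_C_bar=p_C_bar,
        r_bar=r_bar,
        density_T=density_T,
        density_C=density_C,
        m_T_bar=m_T_bar,
        m_Q_bar=m_Q_bar,
        m_C_bar=m_C_bar,
        q_bar=q_bar,
    )
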