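"""State types and mass-action right-hand sides of the two model variants.

The translation model couples two genes through a constant ribosome pool:
the instantaneous free-ribosome level follows a competitive-binding
quasi-steady-state and multiplies both translation rates, so
downregulating one transcript releases capacity onto the other. The
degradation model couples a transgene and an endogenous gene through a
finite RNase pool: mRNAs form degrading mRNA:RNase complexes, and
catalytic completion consumes the mRNA while releasing the RNase.

The miRNA module is shared: free miRNA q binds the target mRNA m_T
(rate ``eta_plus``) into a complex m_Q which is degraded faster; the
miRNA is recycled when the complex is consumed (catalytic RISC), so at
steady state q = alpha_Q / beta_Q.
"""

from __future__ import annotations

from dataclasses import dataclass, astuple

import numpy as np

from .parameters import TranslationParams, DegradationParams


class ModelStateError(ValueError):
    """Raised when a state violates a model constraint (negativity, pools)."""


@dataclass
class TranslationState:
    """Dynamic species of the ribosome-competition model (nM)."""

    m_T: float = 0.0   # free miTarget mRNA
    m_Q: float = 0.0   # miTarget:miRNA complex
    m_C: float = 0.0   # capacity monitor mRNA
    q: float = 0.0     # free miRNA
    p_T: float = 0.0   # miTarget protein
    p_C: float = 0.0   # capacity monitor protein

    def to_array(self) -> np.ndarray:
        return np.array(astuple(self), dtype=float)

    @classmethod
    def from_array(cls, y) -> "TranslationState":
        return cls(*map(float, y))


@dataclass
class DegradationState:
    """Dynamic species of the finite-RNase model (nM).

    The miTarget:RNase complex is split by provenance: ``s_TF`` formed
    from free (miRNA-unbound) mRNA, ``s_TQ`` from the miRNA-bound
    complex. The total ``s_T`` of the reaction scheme is their sum.
    """

    m_T: float = 0.0   # free miTarget mRNA
    m_Q: float = 0.0   # miTarget:miRNA complex
    m_E: float = 0.0   # endogenous mRNA
    q: float = 0.0     # free miRNA
    s_TF: float = 0.0  # miTarget:RNase complex, from free mRNA
    s_TQ: float = 0.0  # miTarget:RNase complex, from miRNA-bound mRNA
    s_E: float = 0.0   # endogenous mRNA:RNase complex

    @property
    def s_T(self) -> float:
        return self.s_TF + self.s_TQ

    def free_rnase(self, params: DegradationParams) -> float:
        return params.z_total - self.s_TF - self.s_TQ - self.s_E

    def to_array(self) -> np.ndarray:
        return np.array(astuple(self), dtype=float)

    @classmethod
    def from_array(cls, y) -> "DegradationState":
        return cls(*map(float, y))


def free_ribosomes(state: TranslationState, params: TranslationParams) -> float:
    """Free-ribosome concentration under competitive binding (nM).

    r_free = r_total / (1 + m_T/kappa_T + sigma * m_Q/kappa_T + m_C/kappa_C)

    The sigma switch gates ribosome sequestration by the miRNA-bound
    complex: with target sites in the 5'UTR (sigma = 0) the complex binds
    no ribosomes (steric hindrance), with 3'UTR sites (sigma = 1) it is
    loaded and translated like the free transcript.
    """
    y = state.to_array() if isinstance(state, TranslationState) else np.asarray(state, float)
    if not np.all(np.isfinite(y)):
        raise ModelStateError(f"non-finite state components: {y}")
    m_T, m_Q, m_C = y[0], y[1], y[2]
    demand = m_T / params.kappa_T + params.sigma * m_Q / params.kappa_T + m_C / params.kappa_C
    return params.r_total / (1.0 + demand)


def translation_rhs(state: TranslationState, params: TranslationParams) -> TranslationState:
    """Time derivatives of the ribosome-competition model (nM/h)."""
    y = state.to_array() if isinstance(state, TranslationState) else np.asarray(state, float)
    dy = _translation_rhs_arr(0.0, y, params)
    return TranslationState.from_array(dy)


def _translation_rhs_arr(t, y, params: TranslationParams) -> np.ndarray:
    p = params
    m_T, m_Q, m_C, q, p_T, p_C = y
    beta_TQ = p.beta_TQ
    bind = p.eta_plus * q * m_T
    r_free = p.r_total / (
        1.0 + m_T / p.kappa_T + p.sigma * m_Q / p.kappa_T + m_C / p.kappa_C
    )
    d_m_T = p.n_T * p.alpha_T - p.beta_T * m_T - bind + p.eta_minus * m_Q
    d_m_Q = bind - (p.eta_minus + beta_TQ) * m_Q
    # miRNA recycled on complex degradation (catalytic RISC)
    d_q = p.alpha_Q - p.beta_Q * q - bind + (p.eta_minus + beta_TQ) * m_Q
    d_m_C = p.n_C * p.alpha_C - p.beta_C * m_C
    d_p_T = p.gamma_T * r_free * (m_T + p.sigma * m_Q) / p.kappa_T - p.delta_T * p_T
    d_p_C = p.gamma_C * r_free * m_C / p.kappa_C - p.delta_C * p_C
    return np.array([d_m_T, d_m_Q, d_m_C, d_q, d_p_T, d_p_C])


def degradation_rhs(
    state: DegradationState,
    params: DegradationParams,
    transcription_on: bool = True,
) -> DegradationState:
    """Time derivatives of the finite-RNase model (nM/h).

    Free RNase is the conserved remainder z = z_total - s_TF - s_TQ - s_E.
    Catalytic completion of a complex consumes the mRNA and releases the
    RNase; complexes formed from the miRNA-bound mRNA additionally
    release the miRNA. ``transcription_on = False`` zeroes all production
    terms (the transcription-halt protocol).
    """
    y = state.to_array() if isinstance(state, DegradationState) else np.asarray(state, float)
    if y[4] + y[5] + y[6] > params.z_total * (1 + 1e-12):
        raise ModelStateError(
            f"bound RNase {y[4] + y[5] + y[6]:g} exceeds total pool {params.z_total:g}"
        )
    dy = _degradation_rhs_arr(0.0, y, params, transcription_on)
    return DegradationState.from_array(dy)


def _degradation_rhs_arr(t, y, params: DegradationParams, on: bool) -> np.ndarray:
    p = params
    m_T, m_Q, m_E, q, s_TF, s_TQ, s_E = y
    z = p.z_total - s_TF - s_TQ - s_E
    bind = p.eta_plus * q * m_T
    on_ = 1.0 if on else 0.0

    d_m_T = (on_ * p.n_T * p.alpha_T - bind + p.eta_minus * m_Q
             - p.betaT_assoc * z * m_T + p.betaT_dissoc * s_TF)
    d_m_Q = (bind - p.eta_minus * m_Q
             - p.betaTQ_assoc * z * m_Q + p.betaT_dissoc * s_TQ)
    d_q = (on_ * p.alpha_Q - p.beta_Q * q - bind + p.eta_minus * m_Q
           + p.betaTQ_cat * s_TQ)
    d_s_TF = p.betaT_assoc * z * m_T - (p.betaT_dissoc + p.betaT_cat) * s_TF
    d_s_TQ = p.betaTQ_assoc * z * m_Q - (p.betaT_dissoc + p.betaTQ_cat) * s_TQ
    d_m_E = (on_ * p.n_E * p.alpha_E - p.betaE_assoc * z * m_E
             + p.betaE_dissoc * s_E)
    d_s_E = p.betaE_assoc * z * m_E - (p.betaE_dissoc + p.betaE_cat) * s_E
    return np.array([d_m_T, d_m_Q, d_m_E, d_q, d_s_TF, d_s_TQ, d_s_E])


def effective_degradation_rate(
    state: DegradationState, params: DegradationParams, species: str
) -> float:
    """Instantaneous first-order equivalent decay rate of one species (1/h).

    The full reaction scheme is summarised by the rate a simple
    exponential-decay model would need at this instant:
    beta_eff = (catalytic degradation flux) / (total free + complexed mRNA).
    For the miTarget the total spans the free, miRNA-bound and complexed
    pools. Raises on an empty pool, where the rate is undefined.
    """
    if species == "endogenous":
        total = state.m_E + state.s_E
        flux = params.betaE_cat * state.s_E
    elif species == "miTarget":
        total = state.m_T + state.m_Q + state.s_TF + state.s_TQ
        flux = params.betaT_cat * state.s_TF + params.betaTQ_cat * state.s_TQ
    else:
        raise ValueError(f"species must be 'miTarget' or 'endogenous', got {species!r}")
    if total <= 0:
        raise ModelStateError(f"effective rate undefined: no {species} mRNA present")
    return flux / total
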