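"""Parameter containers for the two resource-aware model variants.

Two ODE models share a common miRNA module but compete for different
resource pools:

* the *translation* model — two constitutive genes (the miRNA-regulated
  "miTarget" and a constitutive "capacity monitor") competing for a fixed
  pool of ribosomes;
* the *degradation* model — the miTarget and an endogenous gene competing
  for a finite pool of RNases.

Units convention: concentrations in nM, time in hours; second-order
binding constants in nM^-1 h^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict
from importlib import resources
from pathlib import Path

import yaml


class ParameterError(ValueError):
    """Raised when a parameter set violates model constraints."""


def _check_positive(obj, names):
    for name in names:
        v = getattr(obj, name)
        if not (v > 0):
            raise ParameterError(f"{name} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class TranslationParams:
    """Parameters of the ribosome-competition model.

    The miTarget (subscript T) is transcribed from ``n_T`` gene copies,
    bound by a miRNA (subscript Q) with second-order rate ``eta_plus``,
    and translated in competition with the capacity monitor (subscript C)
    for a constant ribosome pool ``r_total``. miRNA binding raises the
    mRNA decay rate to ``lambda_TQ * beta_T``; the boolean ``sigma``
    encodes target-site location (0 = 5'UTR: the miRNA-bound complex is
    translationally silent by steric hindrance; 1 = 3'UTR: the complex is
    still loaded and translated).
    """

    n_T: float = 1.0            # miTarget gene copy number
    n_C: float = 1.0            # capacity monitor gene copy number
    alpha_T: float = 10.0       # miTarget transcription rate (nM/h per copy)
    alpha_C: float = 10.0       # monitor transcription rate (nM/h per copy)
    alpha_Q: float = 0.0015     # miRNA production rate (nM/h)
    beta_T: float = 0.2         # basal miTarget mRNA decay (1/h)
    beta_C: float = 0.2         # monitor mRNA decay (1/h)
    beta_Q: float = 0.5         # miRNA decay (1/h)
    lambda_TQ: float = 10.0     # fold-increase of miRNA-enhanced decay (>1)
    gamma_T: float = 10.0       # miTarget translation rate (1/h)
    gamma_C: float = 10.0       # monitor translation rate (1/h)
    delta_T: float = 0.1        # miTarget protein dilution/decay (1/h)
    delta_C: float = 0.1        # monitor protein dilution/decay (1/h)
    kappa_T: float = 10.0       # effective ribosome-mRNA dissociation (nM)
    kappa_C: float = 10.0       # effective ribosome-mRNA dissociation (nM)
    eta_plus: float = 0.0       # miRNA-mRNA binding constant (nM^-1 h^-1)
    eta_minus: float = 1.0      # complex dissociation rate (1/h)
    sigma: int = 1              # TS location switch: 0 = 5'UTR, 1 = 3'UTR
    r_total: float = 1000.0     # total ribosome pool (nM)

    def __post_init__(self):
        _check_positive(self, [
            "n_T", "n_C", "alpha_T", "alpha_C", "alpha_Q",
            "beta_T", "beta_C", "beta_Q", "gamma_T", "gamma_C",
            "delta_T", "delta_C", "kappa_T", "kappa_C", "r_total",
        ])
        if self.lambda_TQ <= 1:
            raise ParameterError(f"lambda_TQ must exceed 1, got {self.lambda_TQ}")
        if self.sigma not in (0, 1):
            raise ParameterError(f"sigma must be 0 or 1, got {self.sigma!r}")
        if self.eta_plus < 0:
            raise ParameterError(f"eta_plus must be >= 0, got {self.eta_plus}")
        if self.eta_minus <= 0:
            raise ParameterError(f"eta_minus must be > 0, got {self.eta_minus}")

    @property
    def beta_TQ(self) -> float:
        """miRNA-enhanced mRNA decay rate, derived as lambda_TQ * beta_T."""
        return self.lambda_TQ * self.beta_T

    def replace(self, **changes) -> "TranslationParams":
        d = asdict(self)
        d.update(changes)
        return TranslationParams(**d)


@dataclass(frozen=True)
class DegradationParams:
    """Parameters of the finite-RNase degradation model.

    mRNAs bind free RNase (pool ``z_total``) to form degrading complexes;
    catalytic completion consumes the mRNA and releases the RNase. miRNA
    binding to the miTarget raises its RNase association constant from
    ``betaT_assoc`` to ``betaTQ_assoc``, funnelling degradation machinery
    onto the target and away from the endogenous transcript.
    """

    n_T: float = 1.0             # miTarget gene copy number
    n_E: float = 1.0             # endogenous gene copy number
    alpha_T: float = 40.0        # miTarget transcription rate (nM/h per copy)
    alpha_E: float = 20.0        # endogenous transcription rate (nM/h per copy)
    alpha_Q: float = 0.1         # miRNA production rate (nM/h)
    beta_Q: float = 0.2          # miRNA decay (1/h)
    eta_plus: float = 0.0        # miRNA-mRNA binding constant (nM^-1 h^-1)
    eta_minus: float = 1.0       # complex dissociation rate (1/h)
    betaT_assoc: float = 0.02    # basal miTarget-RNase association (nM^-1 h^-1)
    betaTQ_assoc: float = 0.2    # miRNA-boosted association (nM^-1 h^-1)
    betaE_assoc: float = 0.0055  # endogenous-RNase association (nM^-1 h^-1)
    betaT_dissoc: float = 1.0    # miTarget:RNase dissociation (1/h)
    betaE_dissoc: float = 1.0    # endogenous:RNase dissociation (1/h)
    betaT_cat: float = 20.0      # catalytic completion, basal miTarget complex (1/h)
    betaTQ_cat: float = 0.8      # catalytic completion, miRNA-committed complex (1/h)
    betaE_cat: float = 20.0      # catalytic completion, endogenous complex (1/h)
    z_total: float = 60.0        # total RNase pool (nM)

    def __post_init__(self):
        _check_positive(self, [
            "n_T", "n_E", "alpha_T", "alpha_E", "alpha_Q", "beta_Q",
            "betaT_assoc", "betaTQ_assoc", "betaE_assoc",
            "betaT_dissoc", "betaE_dissoc", "betaT_cat", "betaTQ_cat",
            "betaE_cat", "z_total",
        ])
        if self.eta_plus < 0:
            raise ParameterError(f"eta_plus must be >= 0, got {self.eta_plus}")
        if self.eta_minus <= 0:
            raise ParameterError(f"eta_minus must be > 0, got {self.eta_minus}")
        if self.betaTQ_assoc < self.betaT_assoc:
            raise ParameterError(
                "betaTQ_assoc must be >= betaT_assoc (miRNA binding can only "
                "increase the RNase association constant)"
            )

    def replace(self, **changes) -> "DegradationParams":
        d = asdict(self)
        d.update(changes)
        return DegradationParams(**d)


_PARAM_CLASSES = {"translation": TranslationParams, "degradation": DegradationParams}


def load_params(path: str | Path, model: str | None = None):
    """Load a parameter set from a flat YAML key-value file.

    The file may carry a ``model: translation|degradation`` key naming the
    variant; otherwise pass ``model`` explicitly. Unknown keys are
    rejected with the offending key named.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParameterError(f"{path}: expected a mapping of parameter names")
    model = raw.pop("model", model)
    if model not in _PARAM_CLASSES:
        raise ParameterError(
            f"{path}: unknown or missing model variant {model!r}; "
            f"expected one of {sorted(_PARAM_CLASSES)}"
        )
    cls = _PARAM_CLASSES[model]
    valid = {f.name for f in fields(cls)}
    unknown = set(raw) - valid
    if unknown:
        raise ParameterError(
            f"{path}: unknown parameter key(s) {sorted(unknown)} for {model} model"
        )
    return cls(**raw)


def save_params(params, path: str | Path) -> None:
    """Write a parameter set back to YAML (round-trips with load_params)."""
    model = "translation" if isinstance(params, TranslationParams) else "degradation"
    doc = {"model": model, **asdict(params)}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_translation_params(**overrides) -> TranslationParams:
    """Shipped default parameterisation of the translation model."""
    return _load_packaged("translation.yaml", **overrides)


def default_degradation_params(**overrides) -> DegradationParams:
    """Shipped default parameterisation of the finite-RNase model."""
    return _load_packaged("degradation.yaml", **overrides)


def _load_packaged(name, **overrides):
    ref = resources.files("mirella").joinpath("data", name)
    raw = yaml.safe_load(ref.read_text())
    model = raw.pop("model")
    cls = _PARAM_CLASSES[model]
    raw.update(overrides)
    return cls(**raw)
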