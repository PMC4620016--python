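"""hemolc: joint latent-class classification of severely hemorrhaging patients.

A two-part mixture couples a death-censored continuous marker (log cumulative
RBC units at 24 h) with the binary 24-h survival outcome through a latent
class membership, estimated by a multi-start EM algorithm with a closed-form
induced-censoring adjustment.  Posterior class probabilities classify
patients as severely hemorrhaging (SH), an alternative to the conventional
massive-transfusion (MT) rule of >= 10 RBC units in 24 h.
"""

from .classify import (
    BandScheme,
    Comparison2x2,
    classify_posteriors,
    compare_sh_mt,
    default_bands,
    mt_rule,
)
from .data import LatentState, ModelParameters, PatientRecord, TraumaData
from .em import EMConfig, FitResult, bic_scan, e_step, fit_em, m_step, posterior_membership
from .inference import (
    InferenceResult,
    compute_inference,
    empirical_information,
    individual_scores,
    wald_tests,
)
from .likelihood import (
    censored_marker_integral,
    censored_marker_moments,
    log_censored_marker_integral,
    membership_probabilities,
    mortality_probability,
    observed_loglik,
)
from .model import JointLatentClassModel, JointLatentClassResults
from .simulate import (
    SimScenario,
    marginal_class1_probability,
    marginal_mortality,
    simulate_dataset,
)
from .study import StudySummary, run_agreement_study, run_recovery_study, study_config

__version__ = "0.1.0"

__all__ = [
    "BandScheme",
    "Comparison2x2",
    "EMConfig",
    "FitResult",
    "InferenceResult",
    "JointLatentClassModel",
    "JointLatentClassResults",
    "LatentState",
    "ModelParameters",
    "PatientRecord",
    "SimScenario",
    "StudySummary",
    "TraumaData",
    "bic_scan",
    "censored_marker_integral",
    "censored_marker_moments",
    "classify_posteriors",
    "compare_sh_mt",
    "compute_inference",
    "default_bands",
    "e_step",
    "empirical_information",
    "fit_em",
    "individual_scores",
    "log_censored_marker_integral",
    "m_step",
    "marginal_class1_probability",
    "marginal_mortality",
    "membership_probabilities",
    "mortality_probability",
    "mt_rule",
    "observed_loglik",
    "posterior_membership",
    "run_agreement_study",
    "run_recovery_study",
    "simulate_dataset",
    "study_config",
    "wald_tests",
]
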