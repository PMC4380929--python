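"""hepg1s: hepatocyte-specific modeling and analysis of the HGF-driven
G1/S transition.

The package couples an algebraic signaling-input layer to a rule-based
ODE model of cell-cycle entry (Cyclin D1:CDK4, Cyclin E:CDK2, p21, Rb,
E2F-1 and DNA content), calibrates it to immunoblot/DNA-content-style
data by multi-start trust-region least squares in log10 parameter space,
and interrogates the calibrated model with control-coefficient
sensitivity analysis, dose-response/EC50 ranking and Fucci-style
single-cell phase statistics.  A synthetic-data module generates every
input the pipeline consumes.
"""

from .analysis import (
    cdk2_cdk4_fold_excess,
    control_coefficient,
    control_coefficient_table,
    dose_response,
    finite_difference_control,
    fit_hill4,
    half_maximum_dose,
    rank_sensitivities,
    regress_components_vs_proliferation,
    response_surface,
)
from .calibration import (
    FitResult,
    chi2,
    multistart_fit,
    parameter_spread,
    perturb_start,
    select_best,
)
from .fucci import (
    PhaseThresholds,
    classify_phase,
    cumulative_transition_curve,
    derive_thresholds,
    detect_transitions,
    filter_fields,
    snapshot_fractions,
)
from .inputs import InputParams, InputState, estimate_basal_activity, evaluate_inputs, inhibitor_clamps
from .network import ReactionNetwork, generate_network
from .parameters import ParameterSet, default_parameters
from .processing import (
    ErrorModel,
    TimeCourseDataset,
    compute_sem,
    estimate_linear_error,
    normalize_by_calibrator,
    normalize_dataset,
    scale_and_merge,
)
from .rules import attach_observables, default_rules
from .sbml import read_sbml, write_sbml
from .simulate import ExperimentProtocol, SimulationError, Trajectories, compute_observables, simulate
from .synth import (
    HillSpec,
    NoiseSpec,
    TrackGeneratorSpec,
    generate_dna_content,
    generate_dose_response,
    generate_timecourses,
    generate_tracks,
)

__version__ = "0.1.0"


def default_network() -> ReactionNetwork:
    """Expand the default rule set and attach the observable map."""
    net = generate_network(default_rules())
    attach_observables(net)
    return net
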