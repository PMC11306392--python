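"""Stepwise optimisation of the confound-correction strategy.

Starting from the minimal baseline (framewise-displacement censoring at the
0.05 mm preset plus 6-parameter motion regression), candidate corrections
are tried one at a time in a priority order mirroring the correction
catalogue (variance standardisation, DVARS censoring, 24-parameter motion
regression, WM/CSF signal regression, aCompCor, global signal regression,
highpass filtering, ICA-based motion removal). A candidate is kept only if
it improves the quality outcome; otherwise it is reverted. The full audit
trail of tried/kept/reverted steps is returned.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .correction import WorkflowOptions
from .regressors import RegressorSpec

BASELINE_FD_THRESHOLD_MM = 0.05


def baseline_options(**overrides) -> WorkflowOptions:
    """The minimal-correction baseline: FD censoring at 0.05 mm + 6 motion
    parameters (linear detrending and grand-mean scaling are always on)."""
    opt = WorkflowOptions(
        fd_censor_threshold=BASELINE_FD_THRESHOLD_MM,
        regressors=RegressorSpec(mot6=True),
    )
    for k, v in overrides.items():
        setattr(opt, k, v)
    return opt


def _add_variance_standardization(opt: WorkflowOptions) -> None:
    opt.variance_standardization = True


def _add_dvars(opt: WorkflowOptions) -> None:
    opt.dvars_censor = True


def _add_mot24(opt: WorkflowOptions) -> None:
    opt.regressors.mot24 = True


def _add_wm_csf(opt: WorkflowOptions) -> None:
    opt.regressors.wm_signal = True
    opt.regressors.csf_signal = True


def _add_acompcor(opt: WorkflowOptions) -> None:
    opt.regressors.acompcor = True


def _add_gsr(opt: WorkflowOptions) -> None:
    opt.regressors.global_signal = True


def _add_highpass(opt: WorkflowOptions) -> None:
    opt.highpass = 0.01


def _add_aroma(opt: WorkflowOptions) -> None:
    opt.aroma = True


DEFAULT_CANDIDATES: list[tuple[str, Callable[[WorkflowOptions], None]]] = [
    ("variance_standardization", _add_variance_standardization),
    ("dvars_censoring", _add_dvars),
    ("mot24_regression", _add_mot24),
    ("wm_csf_regression", _add_wm_csf),
    ("acompcor_regression", _add_acompcor),
    ("global_signal_regression", _add_gsr),
    ("highpass_filtering", _add_highpass),
    ("ica_aroma", _add_aroma),
]


@dataclass
class OptimizationStep:
    name: str
    kept: bool
    score_before: tuple
    score_after: Optional[tuple]
    error: Optional[str] = None


@dataclass
class OptimizationResult:
    options: WorkflowOptions
    score: tuple
    audit: list[OptimizationStep] = field(default_factory=list)

    @property
    def kept_steps(self) -> list[str]:
        return [s.name for s in self.audit if s.kept]


def optimize_correction(
    evaluator: Callable[[WorkflowOptions], tuple],
    candidates: Optional[Sequence[tuple[str, Callable[[WorkflowOptions], None]]]] = None,
    baseline: Optional[WorkflowOptions] = None,
    target: Optional[Callable[[tuple], bool]] = None,
) -> OptimizationResult:
    """Greedy stepwise search over the candidate corrections.

    ``evaluator`` maps a :class:`WorkflowOptions` to a comparable score
    tuple (higher is better), e.g. (number of scans passing inclusion,
    group variability Dice, negative max confound effect). A candidate is
    kept iff its score strictly improves on the current one. ``target``,
    if given, is a predicate on the score that stops the search early when
    no quality issues remain. Evaluator failures skip the candidate and are
    recorded in the audit.
    """
    opt = baseline if baseline is not None else baseline_options()
    score = evaluator(opt)
    audit: list[OptimizationStep] = []
    for name, apply in candidates if candidates is not None else DEFAULT_CANDIDATES:
        if target is not None and target(score):
            break
        trial = copy.deepcopy(opt)
        apply(trial)
        try:
            trial_score = evaluator(trial)
        except Exception as exc:
            audit.append(OptimizationStep(name, False, score, None, error=str(exc)))
            continue
        if trial_score > score:
            audit.append(OptimizationStep(name, True, score, trial_score))
            opt, score = trial, trial_score
        else:
            audit.append(OptimizationStep(name, False, score, trial_score))
    return OptimizationResult(options=opt, score=score, audit=audit)
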