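"""Stepwise optimisation of the confound-correction strategy.

A small dataset corrupted by a brain-wide artefact starts from the minimal
baseline (FD censoring at 0.05 mm + 6 motion parameters). Candidate
corrections are added one at a time and kept only when the number of scans
passing quality control increases.
"""

import boldqc as bq
from boldqc.optimize import DEFAULT_CANDIDATES, optimize_correction

config = bq.PhantomConfig(
    include_confounds=True,
    confound_types=("global_uniform",),
    confound_amplitude=4.0,
    structured_noise_amplitude=0.2,
)
phantoms = [bq.make_category_fixture("mixed", seed=s, config=config)
            for s in range(4)]


def evaluator(options):
    records = []
    for i, ph in enumerate(phantoms):
        res = bq.run_workflow(ph.ts, ph.motion, options,
                              wm_mask=ph.wm_mask, csf_mask=ph.csf_mask)
        records.append(bq.scan_qc_record(f"scan{i}", res, ph))
    return (len(bq.apply_scan_inclusion(records).kept),)


candidates = [c for c in DEFAULT_CANDIDATES
              if c[0] in ("mot24_regression", "global_signal_regression")]
result = optimize_correction(evaluator, candidates=candidates)

for step in result.audit:
    outcome = "kept" if step.kept else "reverted"
    print(f"{step.name:26s} passing {step.score_before[0]} -> "
          f"{step.score_after[0] if step.score_after else '?'} : {outcome}")
print(f"\nfinal strategy keeps: {result.kept_steps}; "
      f"{result.score[0]}/4 scans pass quality control")
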