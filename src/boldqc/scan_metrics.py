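"""Per-scan QC record assembly: correction output -> dual regression -> metrics.

Glue between the correction workflow, the connectivity module and the QC
metrics: runs dual regression with the scan's prior set (networks +
confound sources), scores network specificity against the canonical map,
confound temporal correlation, and network amplitude, and bundles the
result into a :class:`~boldqc.core.ScanQCRecord`.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .connectivity import dual_regression
from .core import ComponentSet, ScanQCRecord, VolumeMap, map_from_voxels
from .correction import CorrectedScan
from .qc import (
    DEFAULT_QC_SMOOTH_FWHM_MM,
    DEFAULT_TOP_FRACTION,
    confound_correlation,
    cr_sd_map,
    network_amplitude,
    network_specificity,
    threshold_top,
)
from .correction import smooth_spatial


def scan_qc_record(
    scan_id: str,
    corrected: CorrectedScan,
    phantom=None,
    priors: Optional[ComponentSet] = None,
    canonical: Optional[VolumeMap] = None,
    network_index: int = 0,
    fwhm: float = DEFAULT_QC_SMOOTH_FWHM_MM,
    fraction: float = DEFAULT_TOP_FRACTION,
) -> ScanQCRecord:
    """Compute the scan-level QC record from a corrected scan.

    ``priors`` and ``canonical`` default to the phantom's ground-truth prior
    set and first planted network when a phantom is given.
    """
    if priors is None:
        if phantom is None:
            raise ValueError("either priors or a phantom must be supplied")
        priors = phantom.priors()
    if canonical is None:
        if phantom is None:
            raise ValueError("either canonical or a phantom must be supplied")
        canonical = phantom.canonical_map(network_index)
    ts = corrected.cleaned
    mask = ts.mask
    tcs, maps = dual_regression(ts, priors)
    net_ids = priors.select("network")
    conf_ids = priors.select("confound")
    if net_ids.size == 0:
        raise ValueError("prior set contains no network component")
    net = net_ids[min(network_index, net_ids.size - 1)]
    net_map = map_from_voxels(maps[net], mask, kind="connectivity")
    dice_val = network_specificity(net_map, canonical, mask, fwhm=fwhm, fraction=fraction)
    if conf_ids.size:
        corr = confound_correlation(tcs[net], tcs[conf_ids])
    else:
        corr = 0.0
    amp = network_amplitude(net_map, mask)
    crmap = cr_sd_map(corrected.y_cr) if corrected.y_cr is not None else None
    mean_cr = float("nan")
    if crmap is not None:
        canon_sm = smooth_spatial(canonical, fwhm, mask)
        canon_thr = threshold_top(canon_sm, mask, fraction, use_absolute=True)
        sel = canon_thr.in_mask(mask).astype(bool)
        mean_cr = float(crmap.in_mask(mask)[sel].mean())
    return ScanQCRecord(
        scan_id=scan_id,
        dice_specificity=dice_val,
        confound_correlation=float(corr),
        amplitude_l2=amp,
        mean_fd=float(corrected.fd.mean()),
        tdof=corrected.tdof,
        retained_fraction=corrected.retained_fraction,
        cr_sd_map=crmap,
        mean_cr_sd=mean_cr,
    )
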