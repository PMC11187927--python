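"""Reported constants of the TM5/TM6 coupling-selectivity model.

These are the published values of the trained classification stack: the
standardization parameters and principal-component eigenvectors fitted on the
98-receptor homology-model training set (24 Gs : 74 Gi/o), the PC1 decision
threshold, the stump-forest hyperparameters, and the per-group Gaussian
summaries of the three geometric descriptors.  They let the closed-form
decision rule be applied to new receptors without refitting.
"""

from __future__ import annotations

import numpy as np

# Feature order used everywhere: (tm5_len, tm5_tilt, tm6_outward)
FEATURE_NAMES = ("tm5_len", "tm5_tilt", "tm6_outward")

# Standardization fitted on the 98 homology models (lengths in residues,
# angles in degrees).
REPORTED_MEANS = np.array([20.276, 8.474, 18.749])
REPORTED_SCALES = np.array([4.164, 5.264, 9.156])

# Top-2 eigenvectors of the standardized covariance (rows: PC1, PC2).
REPORTED_COMPONENTS = np.array(
    [
        [0.649, 0.569, 0.506],
        [-0.081, -0.609, 0.789],
    ]
)

# Gs is called when the PC1 score strictly exceeds this threshold.
GS_THRESHOLD = 0.7

# Coupling labels.
GS = "GS"
GIO = "GIO"
LABELS = (GS, GIO)

# Stump-forest hyperparameters.  The class weights invert the 24:74 training
# composition so the two classes carry equal total weight (24*74 == 74*24).
N_ESTIMATORS = 15
MAX_FEATURES = 1
BAGGING_FRACTION = 0.7
CLASS_WEIGHT = {GS: 74.0, GIO: 24.0}
DEFAULT_SEED = 2784

# Per-group Gaussian summaries of the descriptors, order
# (tm5_len, tm5_tilt, tm6_outward, tm6_len).  TM6 length is measured but
# excluded from classification; its group centres are the reported medians.
GROUP_MEAN = {
    GS: np.array([23.1, 12.3, 23.8, 20.5]),
    GIO: np.array([18.9, 5.90, 19.7, 22.0]),
}
GROUP_SD = {
    GS: np.array([4.6, 7.1, 8.4, 3.0]),
    GIO: np.array([3.1, 2.9, 7.6, 3.0]),
}

# Training/validation set compositions (n_gs, n_gio).
TRAINING_COMPOSITION = {GS: 24, GIO: 74}
TRUE_SET_COMPOSITION = {GS: 20, GIO: 34}

# Extended-TM anchors: TM5 residues at or past 5.69 (Gs receptors) and TM6
# residues at or past 6.29 toward the cytosol (Gi/o receptors) form the
# non-canonical receptor-Galpha interface.
EXTENDED_TM5_ANCHOR_POSITION = 69
EXTENDED_TM6_ANCHOR_POSITION = 29
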