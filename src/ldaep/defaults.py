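"""Reference values for the healthy-adult LDAEP cohort.

These constants parameterize the synthetic cohort generator and serve as the
worked-example surface for the slope statistic: per-level mean N1/P2/N1P2
amplitudes at the midline channels, the corresponding published mean (SD)
LDAEP slopes, covariate effect sizes (sex, age, hormonal-contraceptive use),
and the marginal distributions of the self-report and cognitive covariates.

Slopes are per-dB regression coefficients; by convention in the LDAEP
literature the column is labelled "uV/10 dB" although the printed numbers are
the raw per-dB coefficients (see docs/methods.md).
"""

from __future__ import annotations

INTENSITIES_DB = (55.0, 65.0, 75.0, 85.0, 95.0)

CHANNELS = ("Fz", "FCz", "Cz")
COMPONENTS = ("N1", "P2", "N1P2")

#: Mean component amplitudes (uV) at 55/65/75/85/95 dB, per channel x component.
REFERENCE_AMPLITUDES = {
    ("Fz", "N1"): (-5.98, -7.06, -7.94, -8.97, -11.33),
    ("Fz", "P2"): (3.21, 4.07, 5.13, 7.17, 8.68),
    ("Fz", "N1P2"): (9.20, 11.12, 13.07, 16.14, 20.01),
    ("FCz", "N1"): (-5.99, -7.15, -8.18, -9.47, -12.34),
    ("FCz", "P2"): (3.66, 4.64, 5.82, 8.47, 10.76),
    ("FCz", "N1P2"): (9.64, 11.79, 14.00, 17.94, 23.10),
    ("Cz", "N1"): (-5.10, -6.089, -7.03, -8.14, -10.58),
    ("Cz", "P2"): (3.28, 4.12, 5.27, 7.55, 9.72),
    ("Cz", "N1P2"): (8.38, 10.20, 12.30, 15.69, 20.29),
}

#: Published cohort mean (SD) of the LDAEP slope, per channel x component.
REFERENCE_SLOPES = {
    ("Fz", "N1"): (-0.126, 0.083),
    ("Fz", "P2"): (0.140, 0.086),
    ("Fz", "N1P2"): (0.267, 0.137),
    ("FCz", "N1"): (-0.150, 0.093),
    ("FCz", "P2"): (0.180, 0.097),
    ("FCz", "N1P2"): (0.331, 0.164),
    ("Cz", "N1"): (-0.130, 0.077),
    ("Cz", "P2"): (0.163, 0.092),
    ("Cz", "N1P2"): (0.293, 0.144),
}

#: N1P2 slope mean per channel (generator base means, uV/dB).
BASE_SLOPE_MEAN = {"Fz": 0.267, "FCz": 0.331, "Cz": 0.293}
#: Marginal between-subject SD of the N1P2 slope per channel.
BASE_SLOPE_SD = {"Fz": 0.137, "FCz": 0.164, "Cz": 0.144}
#: Mean N1P2 peak-to-peak amplitude (uV) at the central 75 dB level.
BASE_AMPLITUDE_75DB = {"Fz": 13.07, "FCz": 14.00, "Cz": 12.30}

# Covariate effects on the N1P2 slope (uV/dB). Sex is coded male = 1 with
# female as reference, so the negative coefficient means lower slopes in men.
BETA_SEX_MALE = -0.084
BETA_AGE_PER_YEAR = -0.003
BETA_HC_USE = 0.101

# Cohort composition
N_SUBJECTS = 100
FEMALE_FRACTION = 0.65
AGE_RANGE_YEARS = (18.0, 71.0)
HC_AGE_CUTOFF = 42.0
#: Fraction of women under the HC age cutoff using hormonal contraceptives (19/43).
HC_FRACTION = 19.0 / 43.0

# Self-report distress instruments: mean, SD, bounds.
BDI_MEAN, BDI_SD, BDI_MAX = 4.83, 5.59, 63
PSS_MEAN, PSS_SD, PSS_MAX = 10.80, 5.46, 40

#: Cognitive domain T-scores: mean, SD. The global index is the domain mean.
COGNITIVE_DOMAINS = {
    "attention_wm": (51.0, 6.93),
    "executive": (54.9, 7.84),
    "processing_speed": (53.8, 5.75),
    "visual_memory": (50.8, 9.44),
    "verbal_memory": (59.5, 8.37),
}

# Stimulation paradigm
TRIALS_PER_LEVEL = 80
ISI_RANGE_MS = (1200.0, 1800.0)
SAMPLING_RATE_HZ = 2048.0
ANALYSIS_RATE_HZ = 512.0

#: Default montage: 10-20 scalp subset incl. the midline analysis channels,
#: the mastoid-adjacent reference pair P9/P10, and one vertical EOG channel.
DEFAULT_MONTAGE = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC1", "FCz", "FC2",
    "C3", "Cz", "C4",
    "P3", "Pz", "P4",
    "O1", "O2",
    "P9", "P10",
    "EOG",
)

EOG_CHANNELS = ("EOG",)
MASTOID_CHANNELS = ("P9", "P10")
MIDLINE_CHANNELS = ("Fz", "FCz", "Cz")

#: Blink propagation to scalp channels, as a fraction of the EOG blink
#: amplitude; values fall off with distance from the eyes.
BLINK_PROPAGATION = {
    "Fp1": 0.50, "Fp2": 0.50, "F7": 0.25, "F3": 0.28, "Fz": 0.30,
    "F4": 0.28, "F8": 0.25, "FC1": 0.18, "FCz": 0.20, "FC2": 0.18,
    "C3": 0.10, "Cz": 0.10, "C4": 0.10, "P3": 0.05, "Pz": 0.05,
    "P4": 0.05, "O1": 0.02, "O2": 0.02, "P9": 0.02, "P10": 0.02,
}

#: Evoked-response topography: channel gain relative to the channel's own
#: target amplitude (midline channels carry their exact subject values; the
#: surrounding scalp carries a scaled copy of the FCz response; the
#: mastoid-adjacent pair is kept evoked-free so linked-mastoid referencing is
#: transparent).
EVOKED_SIDE_GAIN = 0.6
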