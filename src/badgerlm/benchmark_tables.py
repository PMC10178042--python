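"""Published per-class evaluation tables used as metric-arithmetic inputs.

These are the printed test-set results of a SWIR hyperspectral study
classifying pesticide residues (none, Acetamiprid, Malathion, Difenoconazole,
Beta-cypermethrin) on Hami melon with classical classifiers, preprocessing
variants, and metaheuristic-optimized ELMs. Each row is
(accuracy %, precision %, sensitivity %, F1). They serve as independent
inputs for validating the macro-averaging and F1 arithmetic of
:mod:`badgerlm.metrics` — the underlying spectra are not public, so only the
printed numbers themselves can be checked.
"""

from __future__ import annotations

CLASS_ROWS = ("None", "Acetamiprid", "Malathion", "Difenoconazole", "Beta-cypermethrin")

#: model -> {"All": row, class: row}; row = (accuracy %, precision %, sensitivity %, F1)
PUBLISHED_TABLES: dict[str, dict[str, tuple[float, float, float, float]]] = {
    # classical classifiers on raw spectra
    "ELM": {
        "All": (79.50, 80.29, 79.50, 0.7962),
        "None": (75.00, 78.95, 75.00, 0.7692),
        "Acetamiprid": (82.50, 89.19, 82.50, 0.8571),
        "Malathion": (82.50, 73.33, 82.50, 0.7765),
        "Difenoconazole": (82.50, 71.74, 82.50, 0.7674),
        "Beta-cypermethrin": (75.00, 88.24, 75.00, 0.8108),
    },
    "SVM": {
        "All": (77.50, 78.03, 77.50, 0.7760),
        "None": (75.00, 78.95, 75.00, 0.7692),
        "Acetamiprid": (77.50, 86.11, 77.50, 0.8158),
        "Malathion": (75.00, 78.95, 75.00, 0.7692),
        "Difenoconazole": (80.00, 68.09, 80.00, 0.7356),
        "Beta-cypermethrin": (80.00, 78.05, 80.00, 0.7901),
    },
    "PLS-DA": {
        "All": (75.50, 76.42, 75.50, 0.7555),
        "None": (75.00, 76.92, 75.00, 0.7595),
        "Acetamiprid": (67.50, 87.10, 67.50, 0.7606),
        "Malathion": (82.50, 71.74, 82.50, 0.7674),
        "Difenoconazole": (77.50, 67.39, 77.50, 0.7209),
        "Beta-cypermethrin": (75.00, 78.95, 75.00, 0.7692),
    },
    # preprocessing comparison on ELM
    "NM-ELM": {
        "All": (82.00, 82.07, 82.00, 0.8201),
        "None": (85.00, 79.07, 85.00, 0.8193),
        "Acetamiprid": (90.00, 92.31, 90.00, 0.9114),
        "Malathion": (80.00, 82.05, 80.00, 0.8101),
        "Difenoconazole": (80.00, 80.00, 80.00, 0.8000),
        "Beta-cypermethrin": (75.00, 76.92, 75.00, 0.7595),
    },
    "MSC-ELM": {
        "All": (80.50, 80.87, 80.50, 0.8062),
        "None": (82.50, 84.62, 82.50, 0.8354),
        "Acetamiprid": (85.00, 91.89, 85.00, 0.8831),
        "Malathion": (82.50, 78.57, 82.50, 0.8049),
        "Difenoconazole": (75.00, 69.77, 75.00, 0.7229),
        "Beta-cypermethrin": (77.50, 79.49, 77.50, 0.7848),
    },
    "SNV-ELM": {
        "All": (80.00, 80.08, 80.00, 0.8001),
        "None": (82.50, 84.62, 82.50, 0.8354),
        "Acetamiprid": (82.50, 84.62, 82.50, 0.8354),
        "Malathion": (75.00, 76.92, 75.00, 0.7595),
        "Difenoconazole": (82.50, 76.74, 82.50, 0.7952),
        "Beta-cypermethrin": (77.50, 77.50, 77.50, 0.7750),
    },
    # metaheuristic-optimized ELMs on min-max-normalised spectra
    "NM-GA-ELM": {
        "All": (88.50, 88.72, 88.50, 0.8852),
        "None": (90.00, 92.31, 90.00, 0.9114),
        "Acetamiprid": (95.00, 90.48, 95.00, 0.9268),
        "Malathion": (87.50, 92.11, 87.50, 0.8974),
        "Difenoconazole": (82.50, 89.19, 82.50, 0.8571),
        "Beta-cypermethrin": (87.50, 79.55, 87.50, 0.8333),
    },
    "NM-HBA-ELM": {
        "All": (90.50, 90.66, 90.50, 0.9051),
        "None": (95.00, 88.37, 95.00, 0.9157),
        "Acetamiprid": (92.50, 94.87, 92.50, 0.9367),
        "Malathion": (87.50, 94.59, 87.50, 0.9091),
        "Difenoconazole": (90.00, 85.71, 90.00, 0.8780),
        "Beta-cypermethrin": (87.50, 89.74, 87.50, 0.8861),
    },
    "NM-tHBA-ELM": {
        "All": (93.50, 93.73, 93.50, 0.9355),
        "None": (92.50, 88.10, 92.50, 0.9024),
        "Acetamiprid": (95.00, 97.44, 95.00, 0.9620),
        "Malathion": (92.50, 97.37, 92.50, 0.9487),
        "Difenoconazole": (95.00, 88.37, 95.00, 0.9157),
        "Beta-cypermethrin": (92.50, 97.37, 92.50, 0.9487),
    },
}
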