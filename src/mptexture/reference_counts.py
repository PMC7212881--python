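"""Published per-type classification counts of the clinical validation study.

These are the printed test-set results (one biopsy per patient; 204 brain
tumors of ten types plus 14 nontumor brain samples) for single-channel
classification based on CARS, TPEF or SHG texture parameters, together with
the misclassification counts of the combined CARS + TPEF analysis.  They are
inputs to :func:`mptexture.aggregation_mapping.report_from_counts`, which
must reproduce the study's published sensitivity / specificity / correct
rates from them — a fixed-point check on the evaluation arithmetic that
needs no image data.
"""
from __future__ import annotations

from .aggregation_mapping import CLASS_NONTUMOR, CLASS_TUMOR, EvaluationReport, report_from_counts

#: (type_tag, true_label, n, correctly classified per channel)
TEST_SET_BIOPSY_COUNTS: tuple[tuple[str, str, int, dict[str, int]], ...] = (
    ("Astrocytoma WHO I + II",       CLASS_TUMOR,    14, {"CARS": 9,  "TPEF": 14, "SHG": 3}),
    ("Astrocytoma WHO III",          CLASS_TUMOR,    36, {"CARS": 28, "TPEF": 28, "SHG": 19}),
    ("Oligodendroglioma WHO III",    CLASS_TUMOR,    20, {"CARS": 15, "TPEF": 19, "SHG": 7}),
    ("GBM",                          CLASS_TUMOR,    45, {"CARS": 39, "TPEF": 44, "SHG": 15}),
    ("Recurrent GBM",                CLASS_TUMOR,    18, {"CARS": 13, "TPEF": 16, "SHG": 10}),
    ("Metastasis of colon cancer",   CLASS_TUMOR,    12, {"CARS": 12, "TPEF": 12, "SHG": 12}),
    ("Metastasis of lung cancer",    CLASS_TUMOR,    23, {"CARS": 22, "TPEF": 22, "SHG": 17}),
    ("Metastasis of renal cancer",   CLASS_TUMOR,    10, {"CARS": 9,  "TPEF": 10, "SHG": 9}),
    ("Metastasis of breast cancer",  CLASS_TUMOR,    12, {"CARS": 12, "TPEF": 12, "SHG": 9}),
    ("Metastasis of melanoma",       CLASS_TUMOR,    14, {"CARS": 13, "TPEF": 13, "SHG": 10}),
    ("Nontumor brain",               CLASS_NONTUMOR, 14, {"CARS": 13, "TPEF": 12, "SHG": 13}),
)

#: Combined CARS+TPEF analysis: 9 of 204 tumors and 0 of 14 nontumor misclassified.
COMBINED_CARS_TPEF = {
    "n_tumor": 204, "tumor_misclassified": 9,
    "n_nontumor": 14, "nontumor_misclassified": 0,
}

METASTASIS_TYPES = tuple(t for t, lbl, _, _ in TEST_SET_BIOPSY_COUNTS
                         if t.startswith("Metastasis"))


def channel_entries(channel: str) -> list[tuple[str, str, int, int]]:
    """Per-type counts for one channel in ``report_from_counts`` form."""
    return [(t, lbl, n, correct[channel]) for t, lbl, n, correct in TEST_SET_BIOPSY_COUNTS]


def channel_report(channel: str) -> EvaluationReport:
    """Evaluation report computed from the published counts for one channel."""
    return report_from_counts(channel_entries(channel), level="sample")


def combined_report() -> EvaluationReport:
    """Evaluation report for the combined CARS + TPEF analysis."""
    c = COMBINED_CARS_TPEF
    entries = [
        ("Brain tumor", CLASS_TUMOR, c["n_tumor"], c["n_tumor"] - c["tumor_misclassified"]),
        ("Nontumor brain", CLASS_NONTUMOR, c["n_nontumor"],
         c["n_nontumor"] - c["nontumor_misclassified"]),
    ]
    return report_from_counts(entries, level="sample")


def correct_tumor_count(channel: str) -> int:
    """Total correctly classified tumor biopsies for one channel."""
    return sum(c[channel] for _, lbl, _, c in TEST_SET_BIOPSY_COUNTS if lbl == CLASS_TUMOR)


def correct_count(channel: str, types: tuple[str, ...]) -> tuple[int, int]:
    """(n, n_correct) over a subset of types for one channel."""
    rows = [(n, c[channel]) for t, _, n, c in TEST_SET_BIOPSY_COUNTS if t in types]
    return sum(n for n, _ in rows), sum(ok for _, ok in rows)
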