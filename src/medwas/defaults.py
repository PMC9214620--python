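"""Editable default code lists, medication annotations and gold standard.

These tables are package defaults meant to be replaced by site-specific
files in real use.  The ICD code lists are plausible ICD-9-CM / ICD-10
families for multiple birth, ART-resulting pregnancy and infertility; they
are illustrative, not an authoritative clinical list.  The annotation table
contains medications commonly discussed in fertility-treatment and
obstetric pharmacoepidemiology plus synthetic filler ingredients so the
default formulary has 123 ingredient-level medications in roughly 25 drug
classes.  The gold standard is the 15 fertility-treatment ingredients.
"""

from __future__ import annotations

import pandas as pd

# (list_name, code_system, code); a trailing "." marks a family prefix.
_DEFAULT_CODES = [
    ("MB", "ICD-9-CM", "651."),
    ("MB", "ICD-9-CM", "V27.2"),
    ("MB", "ICD-9-CM", "V27.3"),
    ("MB", "ICD-9-CM", "V27.4"),
    ("MB", "ICD-9-CM", "V27.5"),
    ("MB", "ICD-9-CM", "V27.6"),
    ("MB", "ICD-9-CM", "V27.7"),
    ("MB", "ICD-10", "O30."),
    ("MB", "ICD-10", "Z37.2"),
    ("MB", "ICD-10", "Z37.3"),
    ("MB", "ICD-10", "Z37.4"),
    ("MB", "ICD-10", "Z37.5"),
    ("MB", "ICD-10", "Z37.6"),
    ("MB", "ICD-10", "Z37.7"),
    ("ART", "ICD-9-CM", "V23.85"),
    ("ART", "ICD-10", "O09.81"),
    ("ART", "ICD-10", "O09.811"),
    ("ART", "ICD-10", "O09.812"),
    ("ART", "ICD-10", "O09.813"),
    ("ART", "ICD-10", "O09.819"),
    ("INFERTILITY", "ICD-9-CM", "628."),
    ("INFERTILITY", "ICD-10", "N97."),
]

# Ingredient-level annotations: (medication_id, names, generic_name,
# drug_class, pregnancy_category, fertility_flag).  Brand and generic
# names of one ingredient share a medication_id.
_NAMED_MEDICATIONS = [
    # fertility treatment (gold standard, 15 ingredients)
    ("clomiphene", ["clomiphene", "Clomid", "Serophene"], "clomiphene", "fertility treatment", "X", 1),
    ("chorionic-gonadotropin", ["chorionic gonadotropin", "Novarel", "Pregnyl"], "chorionic gonadotropin", "fertility treatment", "X", 1),
    ("menotropins", ["menotropins", "Menopur", "Repronex"], "menotropins", "fertility treatment", "X", 1),
    ("follitropin-alfa", ["follitropin alfa", "Gonal-F"], "follitropin alfa", "fertility treatment", "X", 1),
    ("follitropin-beta", ["follitropin beta", "Follistim"], "follitropin beta", "fertility treatment", "X", 1),
    ("urofollitropin", ["urofollitropin", "Bravelle"], "urofollitropin", "fertility treatment", "X", 1),
    ("estradiol", ["estradiol", "Vivelle", "Estrace"], "estradiol", "fertility treatment", "X", 1),
    ("progesterone", ["progesterone", "Crinone", "Prometrium"], "progesterone", "fertility treatment", "B", 1),
    ("leuprolide", ["leuprolide", "Lupron"], "leuprolide", "fertility treatment", "X", 1),
    ("ganirelix", ["ganirelix", "Antagon"], "ganirelix", "fertility treatment", "X", 1),
    ("cetrorelix", ["cetrorelix", "Cetrotide"], "cetrorelix", "fertility treatment", "X", 1),
    ("letrozole", ["letrozole", "Femara"], "letrozole", "fertility treatment", "X", 1),
    ("bromocriptine", ["bromocriptine", "Parlodel"], "bromocriptine", "fertility treatment", "B", 1),
    ("cabergoline", ["cabergoline", "Dostinex"], "cabergoline", "fertility treatment", "B", 1),
    ("nafarelin", ["nafarelin", "Synarel"], "nafarelin", "fertility treatment", "X", 1),
    # non-fertility medications named in obstetric MWAS contexts
    ("lidocaine-prilocaine", ["lidocaine-prilocaine", "EMLA"], "lidocaine-prilocaine", "pain", "B", 0),
    ("methylprednisolone", ["methylprednisolone", "Medrol"], "methylprednisolone", "corticosteroid", "C", 0),
    ("diazepam", ["diazepam", "Valium"], "diazepam", "benzodiazepine", "D", 0),
    ("amoxicillin", ["amoxicillin", "Amoxil"], "amoxicillin", "antibiotic", "B", 0),
    ("doxycycline", ["doxycycline", "Vibramycin"], "doxycycline", "antibiotic", "D", 0),
    ("medroxyprogesterone", ["medroxyprogesterone acetate", "Provera", "Depo-Provera"], "medroxyprogesterone acetate", "progestin", "X", 0),
    ("albuterol", ["albuterol", "Ventolin", "ProAir"], "albuterol", "asthma", "C", 0),
    ("fluticasone-salmeterol", ["fluticasone propionate and salmeterol", "Advair"], "fluticasone propionate and salmeterol", "asthma", "C", 0),
    ("epinephrine", ["epinephrine", "EpiPen"], "epinephrine", "asthma", "C", 0),
    ("dicyclomine", ["dicyclomine", "Bentyl"], "dicyclomine", "gastrointestinal", "B", 0),
    ("heparin", ["heparin"], "heparin", "anticoagulant", "C", 0),
    ("insulin-aspart", ["insulin aspart, human", "Novolog"], "insulin aspart, human", "antidiabetic", "B", 0),
    ("sumatriptan", ["sumatriptan", "Imitrex"], "sumatriptan", "pain", "C", 0),
    ("oxytocin", ["oxytocin", "Pitocin"], "oxytocin", "obstetric", "unassigned", 0),
    ("lorazepam", ["lorazepam", "Ativan"], "lorazepam", "benzodiazepine", "D", 0),
    ("metformin", ["metformin", "Glucophage"], "metformin", "antidiabetic", "B", 0),
]

_FILLER_CLASSES = [
    "pain", "antibiotic", "antihistamine", "antidepressant", "antiemetic",
    "antihypertensive", "thyroid", "dermatologic", "ophthalmic",
    "anticonvulsant", "antifungal", "antiviral", "statin", "ppi",
    "opioid", "nsaid", "muscle relaxant", "diuretic", "bronchodilator",
    "sedative",
]
_FILLER_CATEGORIES = ["unassigned", "C", "B", "unassigned", "C", "B", "unassigned", "D"]

DEFAULT_N_MEDICATIONS = 123


def default_code_lists() -> pd.DataFrame:
    """Default diagnosis code lists as a (list_name, code_system, code) frame."""
    return pd.DataFrame(_DEFAULT_CODES, columns=["list_name", "code_system", "code"])


def default_annotations(n_medications: int = DEFAULT_N_MEDICATIONS) -> pd.DataFrame:
    """Default ingredient annotation table, long format (one row per raw name).

    Columns: medication_id, name, generic_name, drug_class,
    pregnancy_category, fertility_flag.  Filler ingredients pad the named
    medications up to ``n_medications`` ingredients.
    """
    if n_medications < 1:
        raise ValueError("n_medications must be >= 1")
    rows = []
    entries = list(_NAMED_MEDICATIONS[:n_medications])
    n_filler = n_medications - len(entries)
    for i in range(n_filler):
        mid = f"fillermed{i + 1:03d}"
        cls = _FILLER_CLASSES[i % len(_FILLER_CLASSES)]
        cat = _FILLER_CATEGORIES[i % len(_FILLER_CATEGORIES)]
        entries.append((mid, [mid, f"Brandfill{i + 1:03d}"], mid, cls, cat, 0))
    for mid, names, generic, cls, cat, flag in entries:
        for name in names:
            rows.append((mid, name, generic, cls, cat, flag))
    return pd.DataFrame(
        rows,
        columns=["medication_id", "name", "generic_name", "drug_class",
                 "pregnancy_category", "fertility_flag"],
    )


def default_gold_standard() -> list[str]:
    """Medication ids of the fertility-treatment gold standard."""
    return [m[0] for m in _NAMED_MEDICATIONS if m[5] == 1]


def medication_ids(annotations: pd.DataFrame) -> list[str]:
    """Sorted unique medication ids of an annotation table."""
    return sorted(annotations["medication_id"].unique())
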