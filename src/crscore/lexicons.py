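"""Packaged phrase lexicons for the five rubric entity types.

The five types follow the Revised-IDEA annotation scheme: specific
diagnoses (``Dx``), diagnostic categories (``DC``, e.g. "cardiac", which
never count toward the differential-diagnosis score), prioritization
language (``Prior``), supporting clinical data (``Data``) and linkage
terms connecting data to a diagnosis (``Link``).

All phrases are lowercase. In the default ("easy") generator regime the
five lexicons are pairwise disjoint at the phrase level, so a dictionary
tagger is a perfect oracle on clean synthetic notes; token-level overlap
(e.g. "pulmonary" inside "pulmonary embolism") is permitted and is what
makes the trained tagger non-trivial.
"""

from __future__ import annotations

# Specific diagnoses (Dx) — the entities that count toward the D score.
DIAGNOSES: tuple[str, ...] = (
    "acute pancreatitis",
    "community acquired pneumonia",
    "aspiration pneumonia",
    "congestive heart failure",
    "acute decompensated heart failure",
    "pulmonary embolism",
    "acute coronary syndrome",
    "nstemi",
    "unstable angina",
    "diabetic ketoacidosis",
    "hyperosmolar hyperglycemic state",
    "upper gastrointestinal bleed",
    "lower gastrointestinal bleed",
    "peptic ulcer disease",
    "acute cholecystitis",
    "ascending cholangitis",
    "choledocholithiasis",
    "acute appendicitis",
    "diverticulitis",
    "small bowel obstruction",
    "urinary tract infection",
    "pyelonephritis",
    "acute kidney injury",
    "acute tubular necrosis",
    "prerenal azotemia",
    "obstructive uropathy",
    "nephrolithiasis",
    "hepatic encephalopathy",
    "alcoholic hepatitis",
    "acute viral hepatitis",
    "decompensated cirrhosis",
    "spontaneous bacterial peritonitis",
    "clostridioides difficile colitis",
    "ischemic colitis",
    "mesenteric ischemia",
    "copd exacerbation",
    "asthma exacerbation",
    "pneumothorax",
    "pleural effusion",
    "pulmonary edema",
    "interstitial lung disease",
    "lung abscess",
    "empyema",
    "bacterial meningitis",
    "viral encephalitis",
    "ischemic stroke",
    "transient ischemic attack",
    "intracranial hemorrhage",
    "subarachnoid hemorrhage",
    "status epilepticus",
    "guillain barre syndrome",
    "myasthenia gravis",
    "atrial fibrillation with rapid ventricular response",
    "atrial flutter",
    "complete heart block",
    "infective endocarditis",
    "acute pericarditis",
    "cardiac tamponade",
    "myocarditis",
    "aortic dissection",
    "hypertensive emergency",
    "septic shock",
    "cardiogenic shock",
    "hypovolemic shock",
    "anaphylaxis",
    "cellulitis",
    "necrotizing fasciitis",
    "osteomyelitis",
    "septic arthritis",
    "gout flare",
    "pseudogout",
    "deep vein thrombosis",
    "heparin induced thrombocytopenia",
    "immune thrombocytopenic purpura",
    "thrombotic thrombocytopenic purpura",
    "hemolytic anemia",
    "sickle cell vasoocclusive crisis",
    "tumor lysis syndrome",
    "neutropenic fever",
    "hypercalcemia of malignancy",
    "adrenal insufficiency",
    "thyroid storm",
    "myxedema coma",
    "syndrome of inappropriate antidiuresis",
    "diabetes insipidus",
    "hyponatremia",
    "hyperkalemia",
    "rhabdomyolysis",
    "serotonin syndrome",
    "neuroleptic malignant syndrome",
    "alcohol withdrawal",
    "opioid overdose",
    "acetaminophen toxicity",
    "salicylate toxicity",
    "influenza",
    "covid 19 pneumonia",
    "tuberculosis reactivation",
    "lyme disease",
    "infectious mononucleosis",
    "acute hiv infection",
)

# Diagnostic-category words (DC) — organ-system words that do NOT count
# as specific diagnoses when scoring the differential.
CATEGORIES: tuple[str, ...] = (
    "cardiac",
    "pulmonary",
    "infectious",
    "neurologic",
    "gastrointestinal",
    "renal",
    "hepatic",
    "hematologic",
    "endocrine",
    "rheumatologic",
    "oncologic",
    "toxicologic",
)

# Prioritization-of-diagnosis language (Prior).
PRIORITIZATION: tuple[str, ...] = (
    "most likely",
    "less likely",
    "least likely",
    "highest on the differential",
    "lower on the differential",
    "top of the differential",
    "leading etiology",
    "favored over",
    "cannot rule out",
    "unlikely but possible",
)

# Supporting clinical data (Data).
CLINICAL_DATA: tuple[str, ...] = (
    "elevated troponin",
    "st depressions on ecg",
    "diffuse st elevations on ecg",
    "crackles on auscultation",
    "leukocytosis",
    "left shift on differential count",
    "elevated lactate",
    "fever to 102",
    "hypoxia on room air",
    "bilateral infiltrates on imaging",
    "right lower lobe consolidation",
    "elevated creatinine",
    "bland urine sediment",
    "muddy brown casts",
    "pyuria and bacteriuria",
    "hematemesis",
    "melena on rectal exam",
    "elevated lipase",
    "right upper quadrant tenderness",
    "positive murphy sign",
    "dilated common bile duct on ultrasound",
    "positive blood cultures",
    "elevated d dimer",
    "right heart strain on echocardiogram",
    "tachycardia on presentation",
    "new holosystolic murmur",
    "jugular venous distension",
    "lower extremity pitting edema",
    "elevated bnp",
    "pulmonary vascular congestion on chest film",
    "focal weakness on exam",
    "ketonuria",
    "anion gap acidosis",
    "elevated tsh",
    "low cortisol level",
    "asterixis on exam",
    "elevated ammonia level",
    "thrombocytopenia on smear",
    "schistocytes on smear",
    "elevated creatine kinase",
)

# Linkage terms (Link) — connect data to a diagnosis.
LINKAGE: tuple[str, ...] = (
    "consistent with",
    "supported by",
    "suggestive of",
    "as evidenced by",
    "explained by",
    "attributable to",
    "in the setting of",
    "in the context of",
    "corroborated by",
    "pointing toward",
    "in light of",
    "on the basis of",
    "in keeping with",
    "borne out by",
    "accounted for by",
)

# Filler vocabulary for non-entity prose; kept clear of every lexicon
# phrase so clean synthetic notes contain no accidental entities.
DISTRACTORS: tuple[str, ...] = (
    "reports",
    "endorses",
    "denies",
    "ongoing",
    "intermittent",
    "progressive",
    "chronic",
    "worsening",
    "improving",
    "stable",
    "mild",
    "moderate",
    "severe",
    "generalized",
    "discomfort",
    "fatigue",
    "malaise",
    "poor appetite",
    "decreased oral intake",
    "trouble sleeping",
)

# Small synonym table for runtime text augmentation.
SYNONYMS: dict[str, tuple[str, ...]] = {
    "elevated": ("increased", "raised", "high"),
    "patient": ("pt", "individual"),
    "presents": ("presenting", "arrives"),
    "admitted": ("hospitalized",),
    "likely": ("probable", "plausible"),
    "exam": ("examination",),
    "acute": ("new onset",),
    "chronic": ("longstanding",),
    "severe": ("marked", "profound"),
    "mild": ("slight",),
    "worsening": ("deteriorating",),
    "improving": ("recovering",),
    "fever": ("pyrexia",),
    "consider": ("entertain",),
    "possible": ("conceivable",),
    "history": ("hx",),
    "year": ("yr",),
    "old": ("aged",),
    "monitor": ("observe", "follow"),
    "continue": ("maintain",),
    "reports": ("describes", "notes"),
    "denies": ("disavows",),
    "stable": ("unchanged",),
    "tenderness": ("pain",),
    "bilateral": ("two sided",),
    "positive": ("present",),
    "negative": ("absent",),
    "workup": ("evaluation",),
    "remains": ("stays",),
    "plan": ("intention",),
}


def default_lexicons() -> dict[str, tuple[str, ...]]:
    """Per-entity-type phrase lists keyed by entity type label."""
    return {
        "Dx": DIAGNOSES,
        "DC": CATEGORIES,
        "Prior": PRIORITIZATION,
        "Data": CLINICAL_DATA,
        "Link": LINKAGE,
    }
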