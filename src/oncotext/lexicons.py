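"""Phrase banks used to render synthetic reports and notes.

Each PRISSMM outcome has its own bank of outcome-bearing sentences; the cue
vocabulary of the progression bank is disjoint from that of the response
bank so that a classifier with no context modeling could in principle
separate them.  Distractor phrases reuse another outcome's cue words but are
wrapped in past/historical context ("prior imaging demonstrated ...") and are
only ever placed outside the outcome-bearing section.
"""

from __future__ import annotations

PROGRESSION_PHRASES = (
    "interval enlargement of the dominant mass",
    "disease progression with new lesions",
    "worsening metastatic disease burden",
    "increased size and number of target lesions",
    "enlarging mass with adjacent invasion",
    "progressive disease compared with the prior study",
    "new sites of metastatic involvement identified",
    "worsening tumor burden despite therapy",
)

RESPONSE_PHRASES = (
    "interval decrease in size of the dominant mass",
    "marked treatment response with shrinking lesions",
    "improvement in overall tumor burden",
    "partial response with smaller target lesions",
    "near complete resolution of the measurable disease",
    "decreased size and number of lesions",
    "favorable response to ongoing therapy",
    "regression of previously seen metastatic deposits",
)

STABLE_PHRASES = (
    "stable appearance of the known malignancy",
    "no significant interval change in tumor burden",
    "unchanged measurable disease",
    "stable residual disease without clear change",
    "persistent malignancy, grossly unchanged",
)

NO_CANCER_PHRASES = (
    "no evidence of malignancy",
    "no radiographic evidence of recurrent tumor",
    "no measurable residual neoplasm",
    "continued remission without recurrent tumor",
    "no convincing finding of viable malignancy",
)

SITE_PHRASES = {
    "brain": "metastatic focus in the brain parenchyma",
    "bone": "osseous metastatic involvement of the axial skeleton",
    "adrenal": "metastatic nodule in the adrenal gland",
    "liver": "hepatic metastasis in the right lobe",
    "lung": "pulmonary metastatic nodule",
    "node": "pathologically enlarged metastatic lymph node",
    "peritoneum": "peritoneal carcinomatosis with omental deposits",
}

#: Wrappers that mark a phrase as historical context rather than a current
#: finding; used for distractor insertion outside the outcome-bearing section.
DISTRACTOR_WRAPPERS = (
    "prior imaging at that time demonstrated {phrase}.",
    "records describe earlier {phrase}.",
    "historical documentation noted {phrase}.",
)

IMAGING_FILLER = (
    "the visualized solid organs are otherwise unremarkable.",
    "no acute osseous abnormality is identified.",
    "mild degenerative changes of the spine are noted.",
    "the airways are patent without focal consolidation.",
    "no pericardial effusion is present.",
    "surgical clips are again noted in the operative bed.",
    "small hiatal hernia is incidentally seen.",
    "cholelithiasis without cholecystitis.",
)

NOTE_FILLER = (
    "patient reports adequate oral intake and stable weight.",
    "no new focal neurologic complaints today.",
    "performance status is unchanged from the prior visit.",
    "mild fatigue managed conservatively.",
    "vital signs reviewed and within acceptable limits.",
    "medication list reconciled without changes.",
    "laboratory values reviewed, counts adequate for therapy.",
    "renal and hepatic function remain preserved.",
    "no new rash or arthralgias since the last infusion.",
    "pain well controlled on the current regimen.",
)

PLAN_PHRASES = (
    "continue current systemic therapy and reassess with imaging",
    "will proceed with the next cycle as scheduled",
    "discussed switching to an alternative regimen",
    "plan restaging scans prior to the next visit",
    "supportive care optimized, follow up in clinic",
)

#: Headers accepted as the start of the assessment/plan section (matched
#: case-insensitively).  The generator samples from this same list.
AP_HEADERS = (
    "assessment and plan",
    "assessment/plan",
    "assessment & plan",
    "impression and plan",
    "a/p",
)

#: Headers that terminate a section (any recognized section boundary).
OTHER_SECTION_HEADERS = (
    "chief complaint",
    "history of present illness",
    "interval history",
    "review of systems",
    "medications",
    "physical exam",
    "labs",
    "imaging review",
    "follow up",
)

IMAGING_EXAMS = (
    "ct chest abdomen pelvis with contrast",
    "ct chest with contrast",
    "mri brain with and without contrast",
    "pet/ct skull base to mid thigh",
    "bone scan whole body",
)


def outcome_phrase_bank(outcome: str):
    return {
        "progression": PROGRESSION_PHRASES,
        "response": RESPONSE_PHRASES,
        "stable": STABLE_PHRASES,
        "no_cancer": NO_CANCER_PHRASES,
    }[outcome]
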