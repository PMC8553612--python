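"""Controlled vocabularies used throughout the pipeline."""

# Truth-set classes
DEL = "DEL"
TOL = "TOL"

# Extra simulation / curation classes for variants outside the truth set
INTERMEDIATE = "INTERMEDIATE"
DISCORDANT = "DISCORDANT"

# Harmonized per-variant calls
CALL_DEL = DEL
CALL_TOL = TOL
CALL_INDETERMINATE = "INDETERMINATE"
CALL_MISSING = "MISSING"
CALLS = (CALL_DEL, CALL_TOL, CALL_INDETERMINATE, CALL_MISSING)
DEFINITE_CALLS = (CALL_DEL, CALL_TOL)

# Per-assay outcomes
FUNCTIONAL = "functional"
NONFUNCTIONAL = "nonfunctional"
ASSAY_INTERMEDIATE = "intermediate"
ASSAY_OUTCOMES = (FUNCTIONAL, NONFUNCTIONAL, ASSAY_INTERMEDIATE)

# Variant consequences
MISSENSE = "missense"
CONSEQUENCES = ("missense", "synonymous", "nonsense", "other")

# ClinVar classes
CLINVAR_CLASSES = ("P", "LP", "B", "LB", "VUS", "other")

# Score direction
HIGHER_IS_DELETERIOUS = "higher_is_deleterious"
LOWER_IS_DELETERIOUS = "lower_is_deleterious"
DIRECTIONS = (HIGHER_IS_DELETERIOUS, LOWER_IS_DELETERIOUS)

# Exclusion reasons, in curation precedence order
REASON_NON_MISSENSE = "non-missense"
REASON_SPLICE_FLANK = "splice-flank"
REASON_DISCORDANT = "discordant"
REASON_INTERMEDIATE = "intermediate"
EXCLUSION_REASONS = (
    REASON_NON_MISSENSE,
    REASON_SPLICE_FLANK,
    REASON_DISCORDANT,
    REASON_INTERMEDIATE,
)
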