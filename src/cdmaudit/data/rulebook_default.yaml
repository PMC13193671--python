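# Default completeness rulebook for an OMOP CDM v5.x-style database.
#
# Three blocks:
#   1. missing/special-value checks on 11 table-column pairs (row-counted);
#      the two vocabulary invalid_reason checks are tagged expected_null —
#      that field is NULL by default and populated only when a relationship
#      or drug-strength mapping has been deprecated, so full missingness
#      there signals validity, not incompleteness;
#   2. per-domain unmapped-standard-concept checks (person-counted);
#   3. per-domain 100%-monthly-change checks and the two prescription
#      value-range bounds (days_supply <= 180, quantity <= 600).
rules:
  # -- missing / special-character values ---------------------------------
  - id: concept_relationship.invalid_reason.missing
    kind: missing_or_special
    table: concept_relationship
    column: invalid_reason
    semantic_class: expected_null
  - id: drug_strength.invalid_reason.missing
    kind: missing_or_special
    table: drug_strength
    column: invalid_reason
    semantic_class: expected_null
  - id: vocabulary.vocabulary_version.missing
    kind: missing_or_special
    table: vocabulary
    column: vocabulary_version
  - id: observation.value_as_string.missing
    kind: missing_or_special
    table: observation
    column: value_as_string
  - id: measurement.unit_source_value.missing
    kind: missing_or_special
    table: measurement
    column: unit_source_value
  - id: measurement.value_source_value.missing
    kind: missing_or_special
    table: measurement
    column: value_source_value
  - id: care_site.place_of_service_source_value.missing
    kind: missing_or_special
    table: care_site
    column: place_of_service_source_value
  - id: care_site.care_site_name.missing
    kind: missing_or_special
    table: care_site
    column: care_site_name
  - id: location.state.missing
    kind: missing_or_special
    table: location
    column: state
  - id: death.cause_source_value.missing
    kind: missing_or_special
    table: death
    column: cause_source_value
  - id: drug_exposure.dose_unit_source_value.missing
    kind: missing_or_special
    table: drug_exposure
    column: dose_unit_source_value

  # -- unmapped standard concepts (distinct persons) ----------------------
  - id: person.race.unmapped
    kind: unmapped_concept
    table: person
    column: race_concept_id
    params: {unit: persons}
  - id: person.ethnicity.unmapped
    kind: unmapped_concept
    table: person
    column: ethnicity_concept_id
    params: {unit: persons}
  - id: death.cause.unmapped
    kind: unmapped_concept
    table: death
    column: cause_concept_id
    params: {unit: persons}
  - id: drug_exposure.drug.unmapped
    kind: unmapped_concept
    table: drug_exposure
    column: drug_concept_id
    params: {unit: persons}
  - id: procedure_occurrence.procedure.unmapped
    kind: unmapped_concept
    table: procedure_occurrence
    column: procedure_concept_id
    params: {unit: persons}
  - id: condition_occurrence.condition.unmapped
    kind: unmapped_concept
    table: condition_occurrence
    column: condition_concept_id
    params: {unit: persons}
  - id: condition_era.condition.unmapped
    kind: unmapped_concept
    table: condition_era
    column: condition_concept_id
    params: {unit: persons}
  - id: observation.observation.unmapped
    kind: unmapped_concept
    table: observation
    column: observation_concept_id
    params: {unit: persons}

  # -- 100% monthly event-count change -----------------------------------
  - id: drug_exposure.monthly_change
    kind: temporal_discontinuity
    table: drug_exposure
    column: drug_concept_id
    params: {date_column: drug_exposure_start_date, threshold: 1.0}
  - id: drug_era.monthly_change
    kind: temporal_discontinuity
    table: drug_era
    column: drug_concept_id
    params: {date_column: drug_era_start_date, threshold: 1.0}
  - id: procedure_occurrence.monthly_change
    kind: temporal_discontinuity
    table: procedure_occurrence
    column: procedure_concept_id
    params: {date_column: procedure_date, threshold: 1.0}
  - id: condition_occurrence.monthly_change
    kind: temporal_discontinuity
    table: condition_occurrence
    column: condition_concept_id
    params: {date_column: condition_start_date, threshold: 1.0}
  - id: condition_era.monthly_change
    kind: temporal_discontinuity
    table: condition_era
    column: condition_concept_id
    params: {date_column: condition_era_start_date, threshold: 1.0}
  - id: observation.monthly_change
    kind: temporal_discontinuity
    table: observation
    column: observation_concept_id
    params: {date_column: observation_date, threshold: 1.0}

  # -- prescription value ranges ------------------------------------------
  - id: drug_exposure.days_supply.range
    kind: value_range
    table: drug_exposure
    column: days_supply
    params: {bound: 180, direction: max_le, group_column: drug_concept_id}
  - id: drug_exposure.quantity.range
    kind: value_range
    table: drug_exposure
    column: quantity
    params: {bound: 600, direction: max_le, group_column: drug_concept_id}
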