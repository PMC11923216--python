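columns:
  dataset_id:
    kind: text
    mandatory: true
  round:
    kind: categorical
    allowed:
    - r1
    - r2
    mandatory: true
  respondent_id:
    kind: text
    mandatory: true
  respondent_is_owner:
    kind: flag
    allowed:
    - 'yes'
    - 'no'
  species:
    kind: set
    separator: ;
    allowed:
    - cattle
    - swine
    - poultry
    - salmonids
  language_status:
    kind: categorical
    allowed:
    - english
    - not_english
    - translated
  content_types:
    kind: set
    separator: ;
    allowed:
    - laboratory_results
    - biosecurity
    - production_results
    - treatment
    - clinical_observation
    - animal_movements
    - economic
    - behaviour
  purposes:
    kind: set
    separator: ;
    allowed:
    - production_information
    - surveillance
    - legislation
    - lab_activities
    - other_business
    - research_integration
  collection_sources:
    kind: categorical
    allowed:
    - single_source
    - multiple_same_type
    - multiple_different_type
    - unreported
  collection_mode:
    kind: categorical
    allowed:
    - automated
    - manual
    - unreported
  storage_format:
    kind: categorical
    allowed:
    - relational_database
    - spreadsheet_collection
    - single_spreadsheet
    - pdf_collection
  quality_practices:
    kind: set
    separator: ;
    allowed:
    - closed_formats
    - collector_training
    - manual_checks
    - automated_checks
    - inspection_verification
    - feedback_loops
    - standards_procedures
  contains_personal_data:
    kind: categorical
    allowed:
    - 'yes'
    - 'no'
    - unknown
  data_subject_identified:
    kind: categorical
    allowed:
    - 'yes'
    - 'no'
    - unknown
  data_subject_documented:
    kind: categorical
    allowed:
    - 'yes'
    - 'no'
    - unknown
  data_controller_identified:
    kind: categorical
    allowed:
    - 'yes'
    - 'no'
    - unknown
  data_controller_documented:
    kind: categorical
    allowed:
    - 'yes'
    - 'no'
    - unknown
  data_owner_identified:
    kind: categorical
    allowed:
    - 'yes'
    - 'no'
    - unknown
  data_identifier_present:
    kind: flag
    allowed:
    - 'yes'
    - 'no'
  data_identifying_elements:
    kind: set
    separator: ;
    allowed:
    - name
    - version_or_release_date
    - responsible_organisation
  metadata_identifier_present:
    kind: flag
    allowed:
    - 'yes'
    - 'no'
  metadata_identifying_elements:
    kind: set
    separator: ;
    allowed:
    - name
    - version_or_release_date
    - responsible_organisation
  metadata_exist:
    kind: categorical
    allowed:
    - 'yes'
    - 'no'
    - unknown
  metadata_link_update_mode:
    kind: categorical
    allowed:
    - automatic
    - manual
    - none_or_unknown
  metadata_structure_status:
    kind: categorical
    allowed:
    - standard_schema
    - documented
    - undocumented
  metadata_vocabulary_practice:
    kind: categorical
    allowed:
    - standard
    - retrievable_glossary
    - collaborative
    - owner_defined
    - unknown
  metadata_access_mode:
    kind: categorical
    allowed:
    - documented_protocol
    - url
    - none
  data_access_mode:
    kind: categorical
    allowed:
    - documented_protocol
    - url
    - none
  data_structure_documented:
    kind: categorical
    allowed:
    - 'yes'
    - 'no'
    - unknown
  data_vocabulary_practice:
    kind: categorical
    allowed:
    - standard
    - retrievable_glossary
    - collaborative
    - owner_defined
    - unknown
  rich_metadata_elements:
    kind: categorical
    allowed:
    - all_available
    - one_missing
    - more_missing
  process_documentation:
    kind: categorical
    allowed:
    - full
    - partial
    - none
  licence_status:
    kind: categorical
    allowed:
    - data_and_metadata
    - data_only
    - none
  consent_publication:
    kind: flag
    allowed:
    - 'yes'
    - 'no'
  consent_consortium:
    kind: categorical
    allowed:
    - 'yes'
    - conditional
    - 'no'
  consent_repository:
    kind: flag
    allowed:
    - 'yes'
    - 'no'
mandatory:
- dataset_id
- round
- respondent_id
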