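-- OMOP CDM subset schema, version 5.4-subset-1

CREATE TABLE vocabulary (
  vocabulary_id TEXT NOT NULL,
  vocabulary_name TEXT NOT NULL,
  PRIMARY KEY (vocabulary_id)
);

CREATE TABLE concept (
  concept_id INTEGER NOT NULL,
  concept_name TEXT NOT NULL,
  domain_id TEXT NOT NULL,
  vocabulary_id TEXT NOT NULL,
  concept_code TEXT NOT NULL,
  standard_concept TEXT,
  PRIMARY KEY (concept_id),
  FOREIGN KEY (vocabulary_id) REFERENCES vocabulary (vocabulary_id)
);

CREATE TABLE concept_relationship (
  concept_id_1 INTEGER NOT NULL,
  concept_id_2 INTEGER NOT NULL,
  relationship_id TEXT NOT NULL,
  FOREIGN KEY (concept_id_1) REFERENCES concept (concept_id),
  FOREIGN KEY (concept_id_2) REFERENCES concept (concept_id)
);

CREATE TABLE location (
  location_id INTEGER NOT NULL,
  city TEXT,
  zip TEXT,
  location_source_value TEXT,
  PRIMARY KEY (location_id)
);

CREATE TABLE care_site (
  care_site_id INTEGER NOT NULL,
  care_site_name TEXT,
  place_of_service_concept_id INTEGER,
  care_site_source_value TEXT,
  PRIMARY KEY (care_site_id)
);

CREATE TABLE provider (
  provider_id INTEGER NOT NULL,
  provider_name TEXT,
  care_site_id INTEGER,
  provider_source_value TEXT,
  PRIMARY KEY (provider_id),
  FOREIGN KEY (care_site_id) REFERENCES care_site (care_site_id)
);

CREATE TABLE person (
  person_id INTEGER NOT NULL,
  gender_concept_id INTEGER NOT NULL,
  year_of_birth INTEGER,
  race_concept_id INTEGER NOT NULL,
  ethnicity_concept_id INTEGER NOT NULL,
  location_id INTEGER,
  provider_id INTEGER,
  care_site_id INTEGER,
  person_source_value TEXT,
  gender_source_value TEXT,
  PRIMARY KEY (person_id),
  FOREIGN KEY (gender_concept_id) REFERENCES concept (concept_id),
  FOREIGN KEY (location_id) REFERENCES location (location_id),
  FOREIGN KEY (provider_id) REFERENCES provider (provider_id),
  FOREIGN KEY (care_site_id) REFERENCES care_site (care_site_id)
);

CREATE TABLE observation_period (
  observation_period_id INTEGER NOT NULL,
  person_id INTEGER NOT NULL,
  observation_period_start_date TEXT NOT NULL,
  observation_period_end_date TEXT NOT NULL,
  period_type_concept_id INTEGER NOT NULL,
  PRIMARY KEY (observation_period_id),
  FOREIGN KEY (person_id) REFERENCES person (person_id),
  FOREIGN KEY (period_type_concept_id) REFERENCES concept (concept_id)
);

CREATE TABLE visit_occurrence (
  visit_occurrence_id INTEGER NOT NULL,
  person_id INTEGER NOT NULL,
  visit_concept_id INTEGER NOT NULL,
  visit_start_date TEXT NOT NULL,
  visit_end_date TEXT NOT NULL,
  visit_type_concept_id INTEGER NOT NULL,
  provider_id INTEGER,
  care_site_id INTEGER,
  visit_source_value TEXT,
  PRIMARY KEY (visit_occurrence_id),
  FOREIGN KEY (person_id) REFERENCES person (person_id),
  FOREIGN KEY (visit_concept_id) REFERENCES concept (concept_id),
  FOREIGN KEY (provider_id) REFERENCES provider (provider_id),
  FOREIGN KEY (care_site_id) REFERENCES care_site (care_site_id)
);

CREATE TABLE measurement (
  measurement_id INTEGER NOT NULL,
  person_id INTEGER NOT NULL,
  measurement_concept_id INTEGER NOT NULL,
  measurement_date TEXT NOT NULL,
  measurement_type_concept_id INTEGER NOT NULL,
  value_as_number REAL,
  unit_concept_id INTEGER,
  visit_occurrence_id INTEGER,
  measurement_source_value TEXT,
  measurement_source_concept_id INTEGER,
  unit_source_value TEXT,
  PRIMARY KEY (measurement_id),
  FOREIGN KEY (person_id) REFERENCES person (person_id),
  FOREIGN KEY (measurement_concept_id) REFERENCES concept (concept_id),
  FOREIGN KEY (visit_occurrence_id) REFERENCES visit_occurrence (visit_occurrence_id)
);

CREATE TABLE drug_exposure (
  drug_exposure_id INTEGER NOT NULL,
  person_id INTEGER NOT NULL,
  drug_concept_id INTEGER NOT NULL,
  drug_exposure_start_date TEXT NOT NULL,
  drug_exposure_end_date TEXT NOT NULL,
  drug_type_concept_id INTEGER NOT NULL,
  quantity REAL,
  days_supply INTEGER,
  refills INTEGER,
  visit_occurrence_id INTEGER,
  drug_source_value TEXT,
  drug_source_concept_id INTEGER,
  PRIMARY KEY (drug_exposure_id),
  FOREIGN KEY (person_id) REFERENCES person (person_id),
  FOREIGN KEY (drug_concept_id) REFERENCES concept (concept_id),
  FOREIGN KEY (visit_occurrence_id) REFERENCES visit_occurrence (visit_occurrence_id)
);

CREATE TABLE drug_era (
  drug_era_id INTEGER NOT NULL,
  person_id INTEGER NOT NULL,
  drug_concept_id INTEGER NOT NULL,
  drug_era_start_date TEXT NOT NULL,
  drug_era_end_date TEXT NOT NULL,
  drug_exposure_count INTEGER,
  gap_days INTEGER,
  PRIMARY KEY (drug_era_id),
  FOREIGN KEY (person_id) REFERENCES person (person_id),
  FOREIGN KEY (drug_concept_id) REFERENCES concept (concept_id)
);

CREATE TABLE note (
  note_id INTEGER NOT NULL,
  person_id INTEGER NOT NULL,
  note_date TEXT,
  note_type_concept_id INTEGER NOT NULL,
  note_class_concept_id INTEGER NOT NULL,
  note_title TEXT,
  note_text TEXT NOT NULL,
  encoding_concept_id INTEGER NOT NULL,
  language_concept_id INTEGER NOT NULL,
  visit_occurrence_id INTEGER,
  note_source_value TEXT,
  PRIMARY KEY (note_id),
  FOREIGN KEY (person_id) REFERENCES person (person_id),
  FOREIGN KEY (visit_occurrence_id) REFERENCES visit_occurrence (visit_occurrence_id)
);

CREATE TABLE observation (
  observation_id INTEGER NOT NULL,
  person_id INTEGER NOT NULL,
  observation_concept_id INTEGER NOT NULL,
  observation_date TEXT NOT NULL,
  observation_type_concept_id INTEGER NOT NULL,
  value_as_string TEXT,
  visit_occurrence_id INTEGER,
  observation_source_value TEXT,
  observation_source_concept_id INTEGER,
  PRIMARY KEY (observation_id),
  FOREIGN KEY (person_id) REFERENCES person (person_id),
  FOREIGN KEY (observation_concept_id) REFERENCES concept (concept_id),
  FOREIGN KEY (visit_occurrence_id) REFERENCES visit_occurrence (visit_occurrence_id)
);

CREATE TABLE death (
  person_id INTEGER NOT NULL,
  death_date TEXT NOT NULL,
  death_type_concept_id INTEGER,
  PRIMARY KEY (person_id),
  FOREIGN KEY (person_id) REFERENCES person (person_id)
);

CREATE TABLE etl_audit (
  audit_id INTEGER NOT NULL,
  table_name TEXT NOT NULL,
  row_id INTEGER,
  flag TEXT NOT NULL,
  detail TEXT,
  PRIMARY KEY (audit_id)
);
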