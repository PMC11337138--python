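# Source export XML schema (version 1.0)

One XML document per patient. All dates are ISO-8601 calendar dates
(`YYYY-MM-DD`); there are no times in the source model. Patient and
consultation identifiers are opaque strings. The root element carries
`schema-version`; parsers must reject unknown versions.

```xml
<?xml version='1.0' encoding='UTF-8'?>
<patient id="W100001" schema-version="1.0">
  <demographics>
    <sex>F</sex>                      <!-- optional; M | F -->
    <year-of-birth>1967</year-of-birth>
    <town>Wattrelos</town>
    <country>FR</country>
  </demographics>
  <registration physician="dr-03" date="2014-05-02"/>
  <addresses>
    <address line="12 rue de la Mairie" town="Wattrelos" zip="59150"/>
  </addresses>
  <consultations>
    <!-- a consultation records the four steps of a primary-care visit -->
    <consultation id="W100001-c0001" date="2015-03-01">
      <reason>Douleur abdominale</reason>            <!-- step 1, free text -->
      <interview>Pas de signe de gravite</interview> <!-- step 2, free text -->
      <examination>                                  <!-- step 3, structured -->
        <biometric variable="Poids" value="72.4" unit="kg"/>
      </examination>
      <outcome>                                      <!-- step 4 -->
        <diagnosis>Gastro-enterite aigue</diagnosis>           <!-- optional -->
        <prescription cip="3400930000001" days-supply="30"
                      quantity="1" refills="0"/>               <!-- 0..n -->
        <referral>Adresse au cardiologue</referral>            <!-- optional -->
        <vaccination>Vaccin antigrippal effectue</vaccination> <!-- optional -->
        <supplementary>A revoir dans un mois</supplementary>   <!-- optional -->
      </outcome>
    </consultation>
  </consultations>
  <lab-results>
    <!-- consultation-ref is optional: set when the result set was ordered
         during a known visit; variable/unit spellings are laboratory-specific -->
    <result-set id="W100001-l0001" laboratory="lab-2" date="2016-02-01"
                consultation-ref="W100001-c0001">
      <result variable="create" value="0.93" unit="mg/dl"/>
    </result-set>
  </lab-results>
  <medical-history>
    <history coded="true" code="E11" date="2012-01-15"/>
    <history coded="false" date="2012-01-15">diabetique depuis 2004</history>
  </medical-history>
  <clinical-reports>
    <report date="2016-05-01">Compte rendu cardiologique: examen normal.</report>
  </clinical-reports>
  <death date="2020-06-01"/>          <!-- optional -->
</patient>
```

Element multiplicities: `demographics`, `registration`, `addresses` are
singular; `consultation`, `result-set`, `history`, `report` repeat freely;
`death` appears at most once. `prescription` attributes `days-supply`,
`quantity` and `refills` are optional integers. Free-text elements carry
plain text only — the parts of the source software dedicated to each
consultation step are always explicitly delimited in this schema.
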