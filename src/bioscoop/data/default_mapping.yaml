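# Default CSV column -> record field mapping, matching the columns that
# write_cohort_csv emits.  Medical events occupy five indexed column triples.
mapping:
  donorId: donorId
  collectionId: collectionId
  sampleId: sampleId
  timestamp: timestamp
  dataSource: dataSource
  birthDate: donor.birthDate
  birthPlace: donor.birthPlace
  residencePlace: donor.residencePlace
  sex: donor.sex
  ethnicOrigin: donor.ethnicOrigin
  skinTone: donor.skinTone
  hairColour: donor.hairColour
  eyeColour: donor.eyeColour
  bloodGroup: donor.bloodGroup
  heightCm: anthropometry.heightCm
  weightKg: anthropometry.weightKg
  waistCm: anthropometry.waistCm
  hipCm: anthropometry.hipCm
  armSpanCm: anthropometry.extras.armSpanCm
  headCircumferenceCm: anthropometry.extras.headCircumferenceCm
  whr: anthropometry.whr
  bmi: anthropometry.bmi
  ci: anthropometry.ci
  icd10Code1: medicalEvents[0].icd10Code
  eventType1: medicalEvents[0].eventType
  eventDate1: medicalEvents[0].eventDate
  icd10Code2: medicalEvents[1].icd10Code
  eventType2: medicalEvents[1].eventType
  eventDate2: medicalEvents[1].eventDate
  icd10Code3: medicalEvents[2].icd10Code
  eventType3: medicalEvents[2].eventType
  eventDate3: medicalEvents[2].eventDate
  icd10Code4: medicalEvents[3].icd10Code
  eventType4: medicalEvents[3].eventType
  eventDate4: medicalEvents[3].eventDate
  icd10Code5: medicalEvents[4].icd10Code
  eventType5: medicalEvents[4].eventType
  eventDate5: medicalEvents[4].eventDate
  materialForm: sample.materialForm
dateFormat: "%Y-%m-%d"
missingTokens: ["", "NA", "null"]
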