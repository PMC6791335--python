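{
  "birthPlace": [
    "Gdansk, Poland",
    "Lodz, Poland",
    "Warsaw, Poland",
    "Krakow, Poland",
    "Wroclaw, Poland",
    "Poznan, Poland",
    "Szczecin, Poland",
    "Vilnius, Lithuania",
    "Prague, Czechia",
    "Berlin, Germany",
    "Lviv, Ukraine",
    "Minsk, Belarus"
  ],
  "residencePlace": [
    "Gdansk, Poland",
    "Lodz, Poland",
    "Warsaw, Poland",
    "Krakow, Poland",
    "Wroclaw, Poland",
    "Poznan, Poland",
    "Katowice, Poland",
    "Bialystok, Poland",
    "Torun, Poland",
    "Lublin, Poland"
  ],
  "ethnicOrigin": [
    "Polish",
    "Kashubian",
    "Silesian",
    "Ukrainian",
    "Lithuanian",
    "Belarusian",
    "German",
    "Czech"
  ],
  "sex": ["male", "female"],
  "icd10": [
    "A09",
    "B18.2",
    "C50.9",
    "E11.9",
    "E66.0",
    "F32.1",
    "G40.3",
    "I10",
    "I25.1",
    "J45.1",
    "K35.8",
    "L40.0",
    "M54.5",
    "N20.0"
  ],
  "materialForm": [
    "whole_blood",
    "serum",
    "plasma",
    "dna",
    "rna",
    "saliva",
    "tissue",
    "urine"
  ],
  "extras": {
    "armSpanCm": [140.0, 215.0],
    "headCircumferenceCm": [50.0, 62.0]
  }
}
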