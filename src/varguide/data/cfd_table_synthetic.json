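{
 "comment": "Synthetic CFD-style penalty table: positional decay toward the PAM, transition/transversion/wobble asymmetry, and strongly penalized non-NGG PAM dinucleotides. Keys: mismatch 'pos:guide>offtarget' with pos 1..20 from the PAM-distal end; pam keyed by the last two PAM bases.",
 "mismatch": {
  "10:A>C": 0.186316,
  "10:A>G": 0.341579,
  "10:A>T": 0.186316,
  "10:C>A": 0.186316,
  "10:C>G": 0.186316,
  "10:C>T": 0.341579,
  "10:G>A": 0.434737,
  "10:G>C": 0.186316,
  "10:G>T": 0.186316,
  "10:T>A": 0.186316,
  "10:T>C": 0.403684,
  "10:T>G": 0.186316,
  "11:A>C": 0.173684,
  "11:A>G": 0.318421,
  "11:A>T": 0.173684,
  "11:C>A": 0.173684,
  "11:C>G": 0.173684,
  "11:C>T": 0.318421,
  "11:G>A": 0.405263,
  "11:G>C": 0.173684,
  "11:G>T": 0.173684,
  "11:T>A": 0.173684,
  "11:T>C": 0.376316,
  "11:T>G": 0.173684,
  "12:A>C": 0.161053,
  "12:A>G": 0.295263,
  "12:A>T": 0.161053,
  "12:C>A": 0.161053,
  "12:C>G": 0.161053,
  "12:C>T": 0.295263,
  "12:G>A": 0.375789,
  "12:G>C": 0.161053,
  "12:G>T": 0.161053,
  "12:T>A": 0.161053,
  "12:T>C": 0.348947,
  "12:T>G": 0.161053,
  "13:A>C": 0.148421,
  "13:A>G": 0.272105,
  "13:A>T": 0.148421,
  "13:C>A": 0.148421,
  "13:C>G": 0.148421,
  "13:C>T": 0.272105,
  "13:G>A": 0.346316,
  "13:G>C": 0.148421,
  "13:G>T": 0.148421,
  "13:T>A": 0.148421,
  "13:T>C": 0.321579,
  "13:T>G": 0.148421,
  "14:A>C": 0.135789,
  "14:A>G": 0.248947,
  "14:A>T": 0.135789,
  "14:C>A": 0.135789,
  "14:C>G": 0.135789,
  "14:C>T": 0.248947,
  "14:G>A": 0.316842,
  "14:G>C": 0.135789,
  "14:G>T": 0.135789,
  "14:T>A": 0.135789,
  "14:T>C": 0.294211,
  "14:T>G": 0.135789,
  "15:A>C": 0.123158,
  "15:A>G": 0.225789,
  "15:A>T": 0.123158,
  "15:C>A": 0.123158,
  "15:C>G": 0.123158,
  "15:C>T": 0.225789,
  "15:G>A": 0.287368,
  "15:G>C": 0.123158,
  "15:G>T": 0.123158,
  "15:T>A": 0.123158,
  "15:T>C": 0.266842,
  "15:T>G": 0.123158,
  "16:A>C": 0.110526,
  "16:A>G": 0.202632,
  "16:A>T": 0.110526,
  "16:C>A": 0.110526,
  "16:C>G": 0.110526,
  "16:C>T": 0.202632,
  "16:G>A": 0.257895,
  "16:G>C": 0.110526,
  "16:G>T": 0.110526,
  "16:T>A": 0.110526,
  "16:T>C": 0.239474,
  "16:T>G": 0.110526,
  "17:A>C": 0.097895,
  "17:A>G": 0.179474,
  "17:A>T": 0.097895,
  "17:C>A": 0.097895,
  "17:C>G": 0.097895,
  "17:C>T": 0.179474,
  "17:G>A": 0.228421,
  "17:G>C": 0.097895,
  "17:G>T": 0.097895,
  "17:T>A": 0.097895,
  "17:T>C": 0.212105,
  "17:T>G": 0.097895,
  "18:A>C": 0.085263,
  "18:A>G": 0.156316,
  "18:A>T": 0.085263,
  "18:C>A": 0.085263,
  "18:C>G": 0.085263,
  "18:C>T": 0.156316,
  "18:G>A": 0.198947,
  "18:G>C": 0.085263,
  "18:G>T": 0.085263,
  "18:T>A": 0.085263,
  "18:T>C": 0.184737,
  "18:T>G": 0.085263,
  "19:A>C": 0.072632,
  "19:A>G": 0.133158,
  "19:A>T": 0.072632,
  "19:C>A": 0.072632,
  "19:C>G": 0.072632,
  "19:C>T": 0.133158,
  "19:G>A": 0.169474,
  "19:G>C": 0.072632,
  "19:G>T": 0.072632,
  "19:T>A": 0.072632,
  "19:T>C": 0.157368,
  "19:T>G": 0.072632,
  "1:A>C": 0.3,
  "1:A>G": 0.55,
  "1:A>T": 0.3,
  "1:C>A": 0.3,
  "1:C>G": 0.3,
  "1:C>T": 0.55,
  "1:G>A": 0.7,
  "1:G>C": 0.3,
  "1:G>T": 0.3,
  "1:T>A": 0.3,
  "1:T>C": 0.65,
  "1:T>G": 0.3,
  "20:A>C": 0.06,
  "20:A>G": 0.11,
  "20:A>T": 0.06,
  "20:C>A": 0.06,
  "20:C>G": 0.06,
  "20:C>T": 0.11,
  "20:G>A": 0.14,
  "20:G>C": 0.06,
  "20:G>T": 0.06,
  "20:T>A": 0.06,
  "20:T>C": 0.13,
  "20:T>G": 0.06,
  "2:A>C": 0.287368,
  "2:A>G": 0.526842,
  "2:A>T": 0.287368,
  "2:C>A": 0.287368,
  "2:C>G": 0.287368,
  "2:C>T": 0.526842,
  "2:G>A": 0.670526,
  "2:G>C": 0.287368,
  "2:G>T": 0.287368,
  "2:T>A": 0.287368,
  "2:T>C": 0.622632,
  "2:T>G": 0.287368,
  "3:A>C": 0.274737,
  "3:A>G": 0.503684,
  "3:A>T": 0.274737,
  "3:C>A": 0.274737,
  "3:C>G": 0.274737,
  "3:C>T": 0.503684,
  "3:G>A": 0.641053,
  "3:G>C": 0.274737,
  "3:G>T": 0.274737,
  "3:T>A": 0.274737,
  "3:T>C": 0.595263,
  "3:T>G": 0.274737,
  "4:A>C": 0.262105,
  "4:A>G": 0.480526,
  "4:A>T": 0.262105,
  "4:C>A": 0.262105,
  "4:C>G": 0.262105,
  "4:C>T": 0.480526,
  "4:G>A": 0.611579,
  "4:G>C": 0.262105,
  "4:G>T": 0.262105,
  "4:T>A": 0.262105,
  "4:T>C": 0.567895,
  "4:T>G": 0.262105,
  "5:A>C": 0.249474,
  "5:A>G": 0.457368,
  "5:A>T": 0.249474,
  "5:C>A": 0.249474,
  "5:C>G": 0.249474,
  "5:C>T": 0.457368,
  "5:G>A": 0.582105,
  "5:G>C": 0.249474,
  "5:G>T": 0.249474,
  "5:T>A": 0.249474,
  "5:T>C": 0.540526,
  "5:T>G": 0.249474,
  "6:A>C": 0.236842,
  "6:A>G": 0.434211,
  "6:A>T": 0.236842,
  "6:C>A": 0.236842,
  "6:C>G": 0.236842,
  "6:C>T": 0.434211,
  "6:G>A": 0.552632,
  "6:G>C": 0.236842,
  "6:G>T": 0.236842,
  "6:T>A": 0.236842,
  "6:T>C": 0.513158,
  "6:T>G": 0.236842,
  "7:A>C": 0.224211,
  "7:A>G": 0.411053,
  "7:A>T": 0.224211,
  "7:C>A": 0.224211,
  "7:C>G": 0.224211,
  "7:C>T": 0.411053,
  "7:G>A": 0.523158,
  "7:G>C": 0.224211,
  "7:G>T": 0.224211,
  "7:T>A": 0.224211,
  "7:T>C": 0.485789,
  "7:T>G": 0.224211,
  "8:A>C": 0.211579,
  "8:A>G": 0.387895,
  "8:A>T": 0.211579,
  "8:C>A": 0.211579,
  "8:C>G": 0.211579,
  "8:C>T": 0.387895,
  "8:G>A": 0.493684,
  "8:G>C": 0.211579,
  "8:G>T": 0.211579,
  "8:T>A": 0.211579,
  "8:T>C": 0.458421,
  "8:T>G": 0.211579,
  "9:A>C": 0.198947,
  "9:A>G": 0.364737,
  "9:A>T": 0.198947,
  "9:C>A": 0.198947,
  "9:C>G": 0.198947,
  "9:C>T": 0.364737,
  "9:G>A": 0.464211,
  "9:G>C": 0.198947,
  "9:G>T": 0.198947,
  "9:T>A": 0.198947,
  "9:T>C": 0.431053,
  "9:T>G": 0.198947
 },
 "pam": {
  "AA": 0.0,
  "AC": 0.0,
  "AG": 0.259259,
  "AT": 0.0,
  "CA": 0.0,
  "CC": 0.0,
  "CG": 0.107142,
  "CT": 0.0,
  "GA": 0.069444,
  "GC": 0.022222,
  "GG": 1.0,
  "GT": 0.016129,
  "TA": 0.0,
  "TC": 0.0,
  "TG": 0.038961,
  "TT": 0.0
 }
}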