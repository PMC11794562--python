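{
  "version": 1,
  "mitdb": {
    "train": ["101", "106", "109", "112", "114", "115", "116", "118", "119",
              "122", "124", "201", "203", "205", "207", "208", "215", "220",
              "222", "223", "230", "232"],
    "test": ["100", "103", "105", "111", "113", "117", "121", "123", "200",
             "202", "209", "210", "212", "213", "214", "219", "221", "228",
             "231", "233", "234"]
  },
  "incartdb": {
    "train": ["I03", "I04", "I05", "I08", "I09", "I10", "I11", "I12", "I13",
              "I14", "I16", "I17", "I18", "I19", "I25", "I26", "I27", "I28",
              "I33", "I34", "I35", "I36", "I37", "I44", "I45", "I46", "I47",
              "I48", "I54", "I55", "I56", "I68", "I69", "I70", "I71", "I72",
              "I73", "I74", "I75"],
    "test": ["I01", "I02", "I06", "I07", "I15", "I20", "I21", "I22", "I23",
             "I24", "I29", "I30", "I31", "I32", "I38", "I39", "I40", "I41",
             "I42", "I43", "I49", "I50", "I51", "I52", "I53", "I57", "I58",
             "I59", "I60", "I61", "I62", "I63", "I64", "I65", "I66", "I67"]
  },
  "edb": {
    "train": [],
    "test": ["e0103", "e0104", "e0105", "e0106", "e0108", "e0110", "e0111",
             "e0112", "e0113", "e0114", "e0115", "e0116", "e0118", "e0119",
             "e0121", "e0122", "e0123", "e0124", "e0125", "e0126", "e0127",
             "e0129", "e0133", "e0136", "e0139", "e0147", "e0148", "e0151",
             "e0154", "e0155", "e0159", "e0161", "e0162", "e0163", "e0166",
             "e0170", "e0601", "e0602", "e0604", "e0605", "e0606", "e0609",
             "e0610", "e0611", "e0612", "e0613", "e0615"]
  }
}
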