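{
  "Aminoacyl-tRNA biosynthesis": {
    "members": ["C00062", "C00152", "C00049", "C00025", "C00064", "C00135",
                "C00123", "C00047", "C00073", "C00079", "C00188", "C00078",
                "C00082", "C00037", "C00041", "C00183", "C00065", "C00148",
                "C00097", "C00407"],
    "edges": []
  },
  "Arginine biosynthesis": {
    "members": ["C00025", "C00064", "C00049", "C00077", "C00169", "C00327",
                "C03406", "C00062", "C00122"],
    "edges": [["C00025", "C00064"], ["C00025", "C00077"], ["C00064", "C00169"],
              ["C00169", "C00327"], ["C00077", "C00327"], ["C00327", "C03406"],
              ["C00049", "C03406"], ["C03406", "C00062"], ["C03406", "C00122"]]
  },
  "Lysine degradation": {
    "members": ["C00047", "C00956", "C03793", "C00487", "C01181", "C00026"],
    "edges": [["C00047", "C00956"], ["C00956", "C00026"], ["C00047", "C03793"],
              ["C03793", "C01181"], ["C01181", "C00487"]]
  },
  "Phenylalanine, tyrosine and tryptophan biosynthesis": {
    "members": ["C00079", "C00082", "C00078", "C00108", "C00251", "C00254"],
    "edges": [["C00251", "C00254"], ["C00254", "C00079"], ["C00254", "C00082"],
              ["C00251", "C00108"], ["C00108", "C00078"], ["C00079", "C00082"]]
  },
  "Alanine, aspartate and glutamate metabolism": {
    "members": ["C00049", "C00025", "C00064", "C00152", "C00041", "C00026",
                "C00122", "C00130"],
    "edges": [["C00041", "C00049"], ["C00049", "C00152"], ["C00049", "C00122"],
              ["C00025", "C00064"], ["C00025", "C00026"], ["C00049", "C00025"],
              ["C00049", "C00130"]]
  },
  "Purine metabolism": {
    "members": ["C00212", "C00294", "C00130", "C00262", "C00385", "C00366",
                "C00147", "C00020"],
    "edges": [["C00212", "C00020"], ["C00020", "C00130"], ["C00130", "C00294"],
              ["C00294", "C00262"], ["C00262", "C00385"], ["C00385", "C00366"],
              ["C00147", "C00262"]]
  },
  "Pyrimidine metabolism": {
    "members": ["C00475", "C00299", "C00106", "C00178", "C00055", "C00105"],
    "edges": [["C00055", "C00475"], ["C00475", "C00299"], ["C00299", "C00106"],
              ["C00105", "C00299"], ["C00106", "C00178"]]
  },
  "Histidine metabolism": {
    "members": ["C00135", "C00439", "C00785", "C01929"],
    "edges": [["C00135", "C00785"], ["C00785", "C00439"], ["C00439", "C01929"]]
  },
  "Tryptophan metabolism": {
    "members": ["C00078", "C00108", "C00328", "C00637", "C05635"],
    "edges": [["C00078", "C00328"], ["C00328", "C00108"], ["C00078", "C00637"],
              ["C00637", "C05635"]]
  },
  "Biotin metabolism": {
    "members": ["C00047", "C00120", "C01909", "C01894"],
    "edges": [["C01909", "C01894"], ["C01894", "C00120"], ["C00047", "C00120"]]
  },
  "Glycerophospholipid metabolism": {
    "members": ["C00670", "C00114", "C00307", "C00157"],
    "edges": [["C00157", "C00670"], ["C00670", "C00114"], ["C00114", "C00307"]]
  },
  "Sphingolipid metabolism": {
    "members": ["C00195", "C00319", "C00550", "C01120"],
    "edges": [["C00195", "C00319"], ["C00195", "C00550"], ["C00319", "C01120"]]
  },
  "Nicotinate and nicotinamide metabolism": {
    "members": ["C00153", "C00253", "C00003", "C00857"],
    "edges": [["C00253", "C00857"], ["C00857", "C00003"], ["C00003", "C00153"]]
  },
  "Starch and sucrose metabolism": {
    "members": ["C00031", "C00089", "C00103", "C00208"],
    "edges": [["C00089", "C00031"], ["C00031", "C00103"], ["C00208", "C00031"]]
  }
}
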