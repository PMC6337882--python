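{
  "1":   {"symbol": "P 1",        "centering": "P",
          "symops": ["x,y,z"]},
  "4":   {"symbol": "P 21",       "centering": "P",
          "symops": ["x,y,z", "-x,y+1/2,-z"]},
  "5":   {"symbol": "C 2",        "centering": "C",
          "symops": ["x,y,z", "-x,y,-z"]},
  "19":  {"symbol": "P 21 21 21", "centering": "P",
          "symops": ["x,y,z", "-x+1/2,-y,z+1/2", "-x,y+1/2,-z+1/2", "x+1/2,-y+1/2,-z"]},
  "20":  {"symbol": "C 2 2 21",   "centering": "C",
          "symops": ["x,y,z", "-x,-y,z+1/2", "-x,y,-z+1/2", "x,-y,-z"]},
  "96":  {"symbol": "P 43 21 2",  "centering": "P",
          "symops": ["x,y,z", "-x,-y,z+1/2", "-y+1/2,x+1/2,z+3/4", "y+1/2,-x+1/2,z+1/4",
                     "-x+1/2,y+1/2,-z+3/4", "x+1/2,-y+1/2,-z+1/4", "y,x,-z", "-y,-x,-z+1/2"]},
  "178": {"symbol": "P 61 2 2",   "centering": "P",
          "symops": ["x,y,z", "-y,x-y,z+1/3", "-x+y,-x,z+2/3", "-x,-y,z+1/2", "y,-x+y,z+5/6",
                     "x-y,x,z+1/6", "y,x,-z+1/3", "x-y,-y,-z", "-x,-x+y,-z+2/3", "-y,-x,-z+5/6",
                     "-x+y,y,-z+1/2", "x,x-y,-z+1/6"]},
  "198": {"symbol": "P 21 3",     "centering": "P",
          "symops": ["x,y,z", "-x+1/2,-y,z+1/2", "-x,y+1/2,-z+1/2", "x+1/2,-y+1/2,-z",
                     "z,x,y", "z+1/2,-x+1/2,-y", "-z+1/2,-x,y+1/2", "-z,x+1/2,-y+1/2",
                     "y,z,x", "-y,z+1/2,-x+1/2", "y+1/2,-z+1/2,-x", "-y+1/2,-z,x+1/2"]}
}
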