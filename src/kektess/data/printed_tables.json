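{
 "3": {
  "Gut": [
   10293184,
   88370384,
   391844240,
   1229017952,
   3110525856,
   6800795568
  ],
  "PI": [
   261520,
   1461944,
   4817200,
   12030552,
   25302928,
   47332920
  ],
  "S": [
   7935312,
   67508352,
   297984656,
   932079328,
   2354695504,
   5141520960
  ],
  "Sze": [
   22602448,
   296922164,
   1771941688,
   6984978108,
   21289569952,
   54441498564
  ],
  "Szev": [
   17870172,
   230496884,
   1363540172,
   5347312020,
   16242326140,
   41433430836
  ],
  "Szt": [
   72465728,
   936816092,
   5548185328,
   21772944012,
   66165325248,
   168840774044
  ],
  "Szv": [
   14122936,
   178900160,
   1049163296,
   4093341864,
   12391103016,
   31532413808
  ],
  "W": [
   1529326,
   12892583,
   56651252,
   176719457,
   445629018,
   971766315
  ],
  "We": [
   2441352,
   21357446,
   95542356,
   301219250,
   764945248,
   1676476958
  ],
  "Wve": [
   1932744,
   16595584,
   73574892,
   230728252,
   583866944,
   1276405096
  ],
  "cols": [
   [
    2,
    5
   ],
   [
    3,
    8
   ],
   [
    4,
    11
   ],
   [
    5,
    14
   ],
   [
    6,
    17
   ],
   [
    7,
    20
   ]
  ],
  "regime": "eq",
  "type": "I"
 },
 "4": {
  "Gut": [
   11625280,
   97990320,
   426964400,
   1321733792,
   3312442336,
   7187653584
  ],
  "PI": [
   286504,
   1579944,
   5137720,
   12704568,
   26522888,
   49332744
  ],
  "S": [
   8949992,
   74572496,
   322939352,
   995869824,
   2489185224,
   5390821680
  ],
  "Sze": [
   26031212,
   334230956,
   1953733580,
   7584990380,
   22857516332,
   57945771308
  ],
  "Szev": [
   41091656,
   516150168,
   2984300216,
   11509390152,
   34529108840,
   87252559544
  ],
  "Szt": [
   124424576,
   1565177780,
   9054773640,
   34930954996,
   104812757168,
   264881430580
  ],
  "Szv": [
   16210052,
   198646488,
   1132439628,
   4327184312,
   12897023156,
   32430540184
  ],
  "W": [
   1722529,
   14156655,
   60785723,
   186359801,
   463838173,
   1001303643
  ],
  "We": [
   2761794,
   23703170,
   104161626,
   324060362,
   814813138,
   1772189810
  ],
  "Wve": [
   2181608,
   18339132,
   79752744,
   246548292,
   617258824,
   1338352780
  ],
  "cols": [
   [
    2,
    5
   ],
   [
    3,
    8
   ],
   [
    4,
    11
   ],
   [
    5,
    14
   ],
   [
    6,
    17
   ],
   [
    7,
    20
   ]
  ],
  "regime": "eq",
  "type": "II"
 },
 "5": {
  "Gut": [
   16096080,
   23772112,
   33592128,
   118832080,
   155668576,
   199507072
  ],
  "PI": [
   363720,
   482800,
   618760,
   1819248,
   2215672,
   2651216
  ],
  "S": [
   12386344,
   18267792,
   25785736,
   90702304,
   118735472,
   152082736
  ],
  "Sze": [
   37104636,
   56790072,
   82453956,
   412500280,
   554800556,
   726607952
  ],
  "Szev": [
   31416480,
   50319732,
   75393800,
   336115552,
   469051260,
   632132168
  ],
  "Szt": [
   122929880,
   192389840,
   283733128,
   1332378664,
   1824962996,
   2424617888
  ],
  "Szv": [
   22992284,
   34960304,
   50491572,
   247647280,
   332059920,
   433745600
  ],
  "W": [
   2382825,
   3509404,
   4948263,
   17307562,
   22640917,
   28982536
  ],
  "We": [
   3840674,
   5699828,
   8086526,
   28793524,
   37803722,
   48544840
  ],
  "Wve": [
   3163474,
   4832900,
   7005422,
   23012176,
   30916824,
   40457928
  ],
  "cols": [
   [
    2,
    6
   ],
   [
    2,
    7
   ],
   [
    2,
    8
   ],
   [
    3,
    9
   ],
   [
    3,
    10
   ],
   [
    3,
    11
   ]
  ],
  "regime": "gt",
  "type": "I"
 },
 "6": {
  "Gut": [
   17894240,
   26106992,
   36534384,
   130568400,
   169736320,
   216121280
  ],
  "PI": [
   393104,
   516584,
   656944,
   1950656,
   2360488,
   2809440
  ],
  "S": [
   13754496,
   20042792,
   28020960,
   99313648,
   129050688,
   164258496
  ],
  "Sze": [
   41831848,
   63024532,
   90404464,
   458729552,
   610907812,
   793550696
  ],
  "Szev": [
   65777296,
   98796088,
   141363616,
   707258416,
   940568808,
   1220296896
  ],
  "Szt": [
   199235872,
   299324704,
   428382016,
   2145008984,
   2852962524,
   3701845184
  ],
  "Szv": [
   25849432,
   38707996,
   55250320,
   271762600,
   360917096,
   467700696
  ],
  "W": [
   2643044,
   3846719,
   5372754,
   18846722,
   24482893,
   31155056
  ],
  "We": [
   4275428,
   6266558,
   8802896,
   31661632,
   41247974,
   52618996
  ],
  "Wve": [
   3511224,
   5296216,
   7600984,
   25190464,
   33579148,
   43653584
  ],
  "cols": [
   [
    2,
    6
   ],
   [
    2,
    7
   ],
   [
    2,
    8
   ],
   [
    3,
    9
   ],
   [
    3,
    10
   ],
   [
    3,
    11
   ]
  ],
  "regime": "gt",
  "type": "II"
 },
 "7": {
  "E": [
   516,
   540,
   492,
   1216,
   1264,
   1168
  ],
  "Gut": [
   10293184,
   11625280,
   9070928,
   88370384,
   97990320,
   79424784
  ],
  "PI": [
   261520,
   286504,
   253032,
   1461944,
   1579944,
   1445120
  ],
  "S": [
   7935312,
   8949992,
   7003400,
   67508352,
   74572496,
   60725712
  ],
  "Sze": [
   22602448,
   26031212,
   19484452,
   296922164,
   334230956,
   262471644
  ],
  "Szev": [
   17870172,
   41091656,
   15732036,
   230496884,
   516150168,
   212184156
  ],
  "Szt": [
   72465728,
   124424576,
   63168968,
   936816092,
   1565177780,
   845317884
  ],
  "Szv": [
   14122936,
   16210052,
   12220444,
   178900160,
   198646488,
   158477928
  ],
  "V": [
   396,
   414,
   378,
   926,
   962,
   890
  ],
  "W": [
   1529326,
   1722529,
   1351715,
   12892583,
   14156655,
   11606991
  ],
  "We": [
   2441352,
   2761794,
   2147798,
   21357446,
   23703170,
   19178010
  ],
  "Wve": [
   1932744,
   2181608,
   1704356,
   16595584,
   18339132,
   14921548
  ],
  "cols": [
   "I_n2m5",
   "II_n2m5",
   "old_n2m5",
   "I_n3m8",
   "II_n3m8",
   "old_n3m8"
  ],
  "rows": [
   "V",
   "E",
   "W",
   "We",
   "Wve",
   "Szv",
   "Sze",
   "Szev",
   "Szt",
   "PI",
   "S",
   "Gut"
  ]
 }
}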