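{
  "schema": 1,
  "units": "s",
  "order": 8,
  "coefficients": [
    [
      0,
      0,
      -0.0001385972817955437
    ],
    [
      1,
      0,
      0.3038866731602508
    ],
    [
      0,
      1,
      -0.06447922083532359
    ],
    [
      2,
      0,
      11.800121138212432
    ],
    [
      1,
      1,
      -14.740168364190573
    ],
    [
      0,
      2,
      2.8800535939678853
    ],
    [
      3,
      0,
      74.79106924896351
    ],
    [
      2,
      1,
      -302.168383222324
    ],
    [
      1,
      2,
      268.77942417082414
    ],
    [
      0,
      3,
      -45.892444819708636
    ],
    [
      4,
      0,
      508.05299822271985
    ],
    [
      3,
      1,
      -2117.6363138603765
    ],
    [
      2,
      2,
      3732.579779949975
    ],
    [
      1,
      3,
      -2435.286754575735
    ],
    [
      0,
      4,
      361.6105176167647
    ],
    [
      5,
      0,
      1571.6374061008567
    ],
    [
      4,
      1,
      -9539.088704626913
    ],
    [
      3,
      2,
      21091.128001292673
    ],
    [
      2,
      3,
      -23829.169238184924
    ],
    [
      1,
      4,
      12041.79725836758
    ],
    [
      0,
      5,
      -1565.56862043854
    ],
    [
      6,
      0,
      3304.415802539951
    ],
    [
      5,
      1,
      -22323.910269879398
    ],
    [
      4,
      2,
      64915.21108960569
    ],
    [
      3,
      3,
      -96805.45581833548
    ],
    [
      2,
      4,
      80654.98248206147
    ],
    [
      1,
      5,
      -32980.19447075737
    ],
    [
      0,
      6,
      3790.1444194380647
    ],
    [
      7,
      0,
      2843.7859709389195
    ],
    [
      6,
      1,
      -25993.07623742534
    ],
    [
      5,
      2,
      93547.60109536744
    ],
    [
      4,
      3,
      -182886.80018246092
    ],
    [
      3,
      4,
      206672.19544437947
    ],
    [
      2,
      5,
      -136934.61204095653
    ],
    [
      1,
      6,
      46871.72931910761
    ],
    [
      0,
      7,
      -4808.933918615229
    ],
    [
      8,
      0,
      579.9037048878912
    ],
    [
      7,
      1,
      -8474.211250630544
    ],
    [
      6,
      2,
      44349.58505222623
    ],
    [
      5,
      3,
      -116356.09999591755
    ],
    [
      4,
      4,
      177977.71524664882
    ],
    [
      3,
      5,
      -164649.99994037233
    ],
    [
      2,
      6,
      91336.59052819686
    ],
    [
      1,
      7,
      -26907.502926730638
    ],
    [
      0,
      8,
      2488.9500262079628
    ]
  ],
  "metadata": {
    "rmse_test": 0.0006217973530489909,
    "r_squared_test": 0.9997175686308318,
    "seed": 42,
    "train_fraction": 0.85,
    "grid_spec": {
      "start": 0.0025,
      "stop": 0.505,
      "spacing": 0.0075
    }
  }
}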