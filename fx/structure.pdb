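ATOM      1  CA  ALA A   1      40.000   0.000   0.000  1.00  0.00           C  
ATOM      2  CA  ALA A   2      39.945   2.093   3.171  1.00  0.00           C  
ATOM      3  CA  ALA A   3      39.781   4.181   6.342  1.00  0.00           C  
ATOM      4  CA  ALA A   4      39.508   6.257   9.513  1.00  0.00           C  
ATOM      5  CA  ALA A   5      39.126   8.316  12.684  1.00  0.00           C  
ATOM      6  CA  ALA A   6      38.637  10.353  15.854  1.00  0.00           C  
ATOM      7  CA  ALA A   7      38.042  12.361  19.025  1.00  0.00           C  
ATOM      8  CA  ALA A   8      37.343  14.335  22.196  1.00  0.00           C  
ATOM      9  CA  ALA A   9      36.542  16.269  25.367  1.00  0.00           C  
ATOM     10  CA  ALA A  10      35.640  18.160  28.538  1.00  0.00           C  
ATOM     11  CA  ALA A  11      34.641  20.000  31.709  1.00  0.00           C  
ATOM     12  CA  ALA A  12      33.547  21.786  34.880  1.00  0.00           C  
ATOM     13  CA  ALA A  13      32.361  23.511  38.051  1.00  0.00           C  
ATOM     14  CA  ALA A  14      31.086  25.173  41.222  1.00  0.00           C  
ATOM     15  CA  ALA A  15      29.726  26.765  44.392  1.00  0.00           C  
ATOM     16  CA  ALA A  16      28.284  28.284  47.563  1.00  0.00           C  
ATOM     17  CA  ALA A  17      26.765  29.726  50.734  1.00  0.00           C  
ATOM     18  CA  ALA A  18      25.173  31.086  53.905  1.00  0.00           C  
ATOM     19  CA  ALA A  19      23.511  32.361  57.076  1.00  0.00           C  
ATOM     20  CA  ALA A  20      21.786  33.547  60.247  1.00  0.00           C  
ATOM     21  CA  ALA A  21      20.000  34.641  63.418  1.00  0.00           C  
ATOM     22  CA  ALA A  22      18.160  35.640  66.589  1.00  0.00           C  
ATOM     23  CA  ALA A  23      16.269  36.542  69.759  1.00  0.00           C  
ATOM     24  CA  ALA A  24      14.335  37.343  72.930  1.00  0.00           C  
ATOM     25  CA  ALA A  25      12.361  38.042  76.101  1.00  0.00           C  
ATOM     26  CA  ALA A  26      10.353  38.637  79.272  1.00  0.00           C  
ATOM     27  CA  ALA A  27       8.316  39.126  82.443  1.00  0.00           C  
ATOM     28  CA  ALA A  28       6.257  39.508  85.614  1.00  0.00           C  
ATOM     29  CA  ALA A  29       4.181  39.781  88.785  1.00  0.00           C  
ATOM     30  CA  ALA A  30       2.093  39.945  91.956  1.00  0.00           C  
ATOM     31  CA  ALA A  31       0.000  40.000  95.127  1.00  0.00           C  
ATOM     32  CA  ALA A  32      -2.093  39.945  98.297  1.00  0.00           C  
ATOM     33  CA  ALA A  33      -4.181  39.781 101.468  1.00  0.00           C  
ATOM     34  CA  ALA A  34      -6.257  39.508 104.639  1.00  0.00           C  
ATOM     35  CA  ALA A  35      -8.316  39.126 107.810  1.00  0.00           C  
ATOM     36  CA  ALA A  36     -10.353  38.637 110.981  1.00  0.00           C  
ATOM     37  CA  ALA A  37     -12.361  38.042 114.152  1.00  0.00           C  
ATOM     38  CA  ALA A  38     -14.335  37.343 117.323  1.00  0.00           C  
ATOM     39  CA  ALA A  39     -16.269  36.542 120.494  1.00  0.00           C  
ATOM     40  CA  ALA A  40     -18.160  35.640 123.665  1.00  0.00           C  
ATOM     41  CA  ALA A  41     -20.000  34.641 126.835  1.00  0.00           C  
ATOM     42  CA  ALA A  42     -21.786  33.547 130.006  1.00  0.00           C  
ATOM     43  CA  ALA A  43     -23.511  32.361 133.177  1.00  0.00           C  
ATOM     44  CA  ALA A  44     -25.173  31.086 136.348  1.00  0.00           C  
ATOM     45  CA  ALA A  45     -26.765  29.726 139.519  1.00  0.00           C  
ATOM     46  CA  ALA A  46     -28.284  28.284 142.690  1.00  0.00           C  
ATOM     47  CA  ALA A  47     -29.726  26.765 145.861  1.00  0.00           C  
ATOM     48  CA  ALA A  48     -31.086  25.173 149.032  1.00  0.00           C  
ATOM     49  CA  ALA A  49     -32.361  23.511 152.202  1.00  0.00           C  
ATOM     50  CA  ALA A  50     -33.547  21.786 155.373  1.00  0.00           C  
ATOM     51  CA  ALA A  51     -34.641  20.000 158.544  1.00  0.00           C  
ATOM     52  CA  ALA A  52     -35.640  18.160 161.715  1.00  0.00           C  
ATOM     53  CA  ALA A  53     -36.542  16.269 164.886  1.00  0.00           C  
ATOM     54  CA  ALA A  54     -37.343  14.335 168.057  1.00  0.00           C  
ATOM     55  CA  ALA A  55     -38.042  12.361 171.228  1.00  0.00           C  
ATOM     56  CA  ALA A  56     -38.637  10.353 174.399  1.00  0.00           C  
ATOM     57  CA  ALA A  57     -39.126   8.316 177.570  1.00  0.00           C  
ATOM     58  CA  ALA A  58     -39.508   6.257 180.740  1.00  0.00           C  
ATOM     59  CA  ALA A  59     -39.781   4.181 183.911  1.00  0.00           C  
ATOM     60  CA  ALA A  60     -39.945   2.093 187.082  1.00  0.00           C  
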