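"""Amino-acid exchangeability data (Dayhoff family) used by the PAM distance.

Lower-triangle exchangeabilities and equilibrium frequencies in the order
A R N D C Q E G H I L K M F P S T W Y V.
"""

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

# exchangeability row i holds S[i+1][j] for j <= i (symmetric matrix, zero diagonal)
EXCHANGEABILITIES = [
    [27.00],
    [98.00, 32.00],
    [120.00, 0.00, 905.00],
    [36.00, 23.00, 0.00, 0.00],
    [89.00, 246.00, 103.00, 134.00, 0.00],
    [198.00, 1.00, 148.00, 1153.00, 0.00, 716.00],
    [240.00, 9.00, 139.00, 125.00, 11.00, 28.00, 81.00],
    [23.00, 240.00, 535.00, 86.00, 28.00, 606.00, 43.00, 10.00],
    [65.00, 64.00, 77.00, 24.00, 44.00, 18.00, 61.00, 0.00, 7.00],
    [41.00, 15.00, 34.00, 0.00, 0.00, 73.00, 11.00, 7.00, 44.00, 257.00],
    [26.00, 464.00, 318.00, 71.00, 0.00, 153.00, 83.00, 27.00, 26.00, 46.00, 18.00],
    [72.00, 90.00, 1.00, 0.00, 0.00, 114.00, 30.00, 17.00, 0.00, 336.00, 527.00, 243.00],
    [18.00, 14.00, 14.00, 0.00, 0.00, 0.00, 0.00, 15.00, 48.00, 196.00, 157.00, 0.00, 92.00],
    [250.00, 103.00, 42.00, 13.00, 19.00, 153.00, 51.00, 34.00, 94.00, 12.00, 32.00, 33.00, 17.00, 11.00],
    [409.00, 154.00, 495.00, 95.00, 161.00, 56.00, 79.00, 234.00, 35.00, 24.00, 17.00, 96.00, 62.00, 46.00, 245.00],
    [371.00, 26.00, 229.00, 66.00, 16.00, 53.00, 34.00, 30.00, 22.00, 192.00, 33.00, 136.00, 104.00, 13.00, 78.00, 550.00],
    [0.00, 201.00, 23.00, 0.00, 0.00, 0.00, 0.00, 0.00, 27.00, 0.00, 46.00, 0.00, 0.00, 76.00, 0.00, 75.00, 0.00],
    [24.00, 8.00, 95.00, 0.00, 96.00, 0.00, 22.00, 0.00, 127.00, 37.00, 28.00, 13.00, 0.00, 698.00, 0.00, 34.00, 42.00, 61.00],
    [208.00, 24.00, 15.00, 18.00, 49.00, 35.00, 37.00, 54.00, 44.00, 889.00, 175.00, 10.00, 258.00, 12.00, 48.00, 30.00, 157.00, 0.00, 28.00],
]

FREQUENCIES = [0.087127, 0.040904, 0.040432, 0.046872, 0.033474, 0.038255, 0.049530, 0.088612, 0.033618, 0.036886, 0.085357, 0.080482, 0.014753, 0.039772, 0.050680, 0.069577, 0.058542, 0.010494, 0.029916, 0.064718]
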