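# synthetic quasi-chemical-style contact-potential substitution score
# symmetric: -(0.25*|dH| + 1.2*|dQ| + 0.008*|dV|); units arbitrary
       A      R      N      D      C      Q      E      G      H      I      L      K      M      F      P      S      T      W      Y      V
A -0.000 -3.453 -1.529 -2.705 -0.334 -1.767 -2.923 -0.778 -2.367 -1.300 -1.125 -3.265 -0.619 -1.060 -1.043 -0.653 -0.845 -1.789 -1.615 -1.011
R -3.453 -0.000 -1.924 -3.148 -3.469 -1.687 -2.930 -3.131 -1.087 -3.504 -3.329 -0.188 -2.884 -3.157 -2.411 -2.800 -2.608 -2.535 -2.162 -3.642
N -1.529 -1.924 -0.000 -1.224 -1.545 -0.238 -1.394 -1.207 -0.988 -2.421 -2.246 -1.736 -1.740 -2.181 -0.486 -0.876 -0.716 -1.560 -1.186 -2.132
D -2.705 -3.148 -1.224 -0.000 -2.721 -1.462 -0.218 -2.383 -2.212 -3.645 -3.470 -2.960 -2.964 -3.405 -1.688 -2.052 -1.940 -2.784 -2.410 -3.356
C -0.334 -3.469 -1.545 -2.721 -0.000 -1.782 -2.939 -1.112 -2.383 -0.966 -0.791 -3.281 -0.585 -0.726 -1.059 -0.981 -0.861 -1.804 -1.631 -0.677
Q -1.767 -1.687 -0.238 -1.462 -1.782 -0.000 -1.243 -1.445 -0.750 -2.183 -2.008 -1.498 -1.503 -1.944 -0.724 -1.113 -0.922 -1.322 -0.948 -1.955
E -2.923 -2.930 -1.394 -0.218 -2.939 -1.243 -0.000 -2.601 -1.993 -3.426 -3.251 -2.742 -2.746 -3.187 -1.881 -2.270 -2.078 -2.565 -2.192 -3.138
G -0.778 -3.131 -1.207 -2.383 -1.112 -1.445 -2.601 -0.000 -2.045 -2.078 -1.903 -2.943 -1.397 -1.838 -0.721 -0.331 -0.523 -1.467 -1.293 -1.789
H -2.367 -1.087 -0.988 -2.212 -2.383 -0.750 -1.993 -2.045 -0.000 -2.633 -2.458 -0.898 -1.953 -2.394 -1.324 -1.714 -1.522 -1.772 -1.398 -2.556
I -1.300 -3.504 -2.421 -3.645 -0.966 -2.183 -3.426 -2.078 -2.633 -0.000 -0.175 -3.315 -0.680 -0.611 -1.957 -1.947 -1.705 -1.839 -1.665 -0.289
L -1.125 -3.329 -2.246 -3.470 -0.791 -2.008 -3.251 -1.903 -2.458 -0.175 -0.000 -3.140 -0.505 -0.436 -1.782 -1.772 -1.530 -1.664 -1.490 -0.314
K -3.265 -0.188 -1.736 -2.960 -3.281 -1.498 -2.742 -2.943 -0.898 -3.315 -3.140 -0.000 -2.696 -3.045 -2.222 -2.612 -2.420 -2.424 -2.050 -3.454
M -0.619 -2.884 -1.740 -2.964 -0.585 -1.503 -2.746 -1.397 -1.953 -0.680 -0.505 -2.696 -0.000 -0.441 -1.277 -1.266 -1.024 -1.219 -1.046 -0.758
F -1.060 -3.157 -2.181 -3.405 -0.726 -1.944 -3.187 -1.838 -2.394 -0.611 -0.436 -3.045 -0.441 -0.000 -1.718 -1.707 -1.465 -1.228 -1.055 -0.749
P -1.043 -2.411 -0.486 -1.688 -1.059 -0.724 -1.881 -0.721 -1.324 -1.957 -1.782 -2.222 -1.277 -1.718 -0.000 -0.390 -0.252 -1.096 -0.722 -1.668
S -0.653 -2.800 -0.876 -2.052 -0.981 -1.113 -2.270 -0.331 -1.714 -1.947 -1.772 -2.612 -1.266 -1.707 -0.390 -0.000 -0.242 -1.135 -0.962 -1.658
T -0.845 -2.608 -0.716 -1.940 -0.861 -0.922 -2.078 -0.523 -1.522 -1.705 -1.530 -2.420 -1.024 -1.465 -0.252 -0.242 -0.000 -0.944 -0.770 -1.416
W -1.789 -2.535 -1.560 -2.784 -1.804 -1.322 -2.565 -1.467 -1.772 -1.839 -1.664 -2.424 -1.219 -1.228 -1.096 -1.135 -0.944 -0.000 -0.374 -1.977
Y -1.615 -2.162 -1.186 -2.410 -1.631 -0.948 -2.192 -1.293 -1.398 -1.665 -1.490 -2.050 -1.046 -1.055 -0.722 -0.962 -0.770 -0.374 -0.000 -1.804
V -1.011 -3.642 -2.132 -3.356 -0.677 -1.955 -3.138 -1.789 -2.556 -0.289 -0.314 -3.454 -0.758 -0.749 -1.668 -1.658 -1.416 -1.977 -1.804 -0.000
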