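# BL62: raw-scale odds-ratio kernel matrix underlying BLOSUM62
# (BLOSUM62-2): entry(i,j) = q_ij / (p_i p_j), from the unrounded
# BLOSUM62 joint target frequencies. Symmetric, positive definite.
A C D E F G H I K L M N P Q R S T V W Y
A 3.902941 0.867988 0.544605 0.741264 0.464894 1.056870 0.569365 0.632481 0.775390 0.601946 0.723150 0.588308 0.754121 0.756804 0.612699 1.472104 0.984402 0.936458 0.416549 0.542612
C 0.867988 19.576586 0.301454 0.285935 0.438990 0.420388 0.355050 0.653459 0.349128 0.642276 0.611354 0.397803 0.379563 0.365782 0.308939 0.738416 0.740552 0.755844 0.449984 0.434203
D 0.544605 0.301454 7.397927 1.687811 0.298969 0.634301 0.678559 0.339015 0.784090 0.286613 0.346455 1.553853 0.598717 0.897081 0.573200 0.913505 0.694790 0.336500 0.232102 0.345684
E 0.741264 0.285935 1.687811 5.469526 0.330744 0.481268 0.960041 0.330523 1.308279 0.372874 0.500342 0.911298 0.679203 1.901738 0.960798 0.950357 0.741426 0.428943 0.374300 0.496467
F 0.464894 0.438990 0.298969 0.330744 8.128797 0.340641 0.651991 0.945770 0.344043 1.154597 1.004372 0.354289 0.287445 0.333972 0.380726 0.439974 0.481694 0.745090 1.374379 2.769381
G 1.056870 0.420388 0.634301 0.481268 0.340641 6.876307 0.492967 0.275010 0.588872 0.284504 0.395487 0.863711 0.477386 0.538650 0.449984 0.903597 0.579272 0.336955 0.421690 0.348714
H 0.569365 0.355050 0.678559 0.960041 0.651991 0.492967 13.506000 0.326288 0.778887 0.380675 0.584133 1.222001 0.472880 1.167981 0.917048 0.736732 0.557503 0.339447 0.444089 1.797904
I 0.632481 0.653459 0.339015 0.330523 0.945770 0.275010 0.326288 3.997930 0.396373 1.694435 1.477745 0.327935 0.384663 0.382938 0.354751 0.443164 0.779816 2.417512 0.408874 0.630389
K 0.775390 0.349128 0.784090 1.308279 0.344043 0.588872 0.778887 0.396373 4.764337 0.428270 0.625303 0.939841 0.703774 1.554323 2.076809 0.931919 0.792906 0.456543 0.358930 0.532179
L 0.601946 0.642276 0.286613 0.372874 1.154597 0.284504 0.380675 1.694435 0.428270 3.796621 1.994296 0.310043 0.371122 0.477326 0.473919 0.428894 0.660329 1.314236 0.568037 0.692059
M 0.723150 0.611354 0.346455 0.500342 1.004372 0.395487 0.584133 1.477745 0.625303 1.994296 6.481451 0.474530 0.423898 0.864250 0.622623 0.598559 0.793802 1.268937 0.610296 0.708365
N 0.588308 0.397803 1.553853 0.911298 0.354289 0.863711 1.222001 0.327935 0.939841 0.310043 0.474530 7.094095 0.499933 1.000584 0.858630 1.231529 0.984153 0.369034 0.277783 0.486031
P 0.754121 0.379563 0.598717 0.679203 0.287445 0.477386 0.472880 0.384663 0.703774 0.371122 0.423898 0.499933 12.837544 0.641281 0.481535 0.755503 0.688897 0.443083 0.281833 0.363521
Q 0.756804 0.365782 0.897081 1.901738 0.333972 0.538650 1.167981 0.382938 1.554323 0.477326 0.864250 1.000584 0.641281 6.244422 1.405796 0.965555 0.791321 0.466778 0.509360 0.611094
R 0.612699 0.308939 0.573200 0.960798 0.380726 0.449984 0.917048 0.354751 2.076809 0.473919 0.622623 0.858630 0.481535 1.405796 6.665577 0.767166 0.677755 0.420072 0.395102 0.555965
S 1.472104 0.738416 0.913505 0.950357 0.439974 0.903597 0.736732 0.443164 0.931919 0.428894 0.598559 1.231529 0.755503 0.965555 0.767166 3.842847 1.613921 0.565224 0.385303 0.557520
T 0.984402 0.740552 0.694790 0.741426 0.481694 0.579272 0.557503 0.779816 0.792906 0.660329 0.793802 0.984153 0.688897 0.791321 0.677755 1.613921 4.832105 0.980943 0.430934 0.573157
V 0.936458 0.755844 0.336500 0.428943 0.745090 0.336955 0.339447 2.417512 0.456543 1.314236 1.268937 0.369034 0.443083 0.466778 0.420072 0.565224 0.980943 3.692156 0.374456 0.658039
W 0.416549 0.449984 0.232102 0.374300 1.374379 0.421690 0.444089 0.408874 0.358930 0.568037 0.610296 0.277783 0.281833 0.509360 0.395102 0.385303 0.430934 0.374456 38.107783 2.109808
Y 0.542612 0.434203 0.345684 0.496467 2.769381 0.348714 1.797904 0.630389 0.532179 0.692059 0.708365 0.486031 0.363521 0.611094 0.555965 0.557520 0.573157 0.658039 2.109808 9.832203
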