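>SYN0001.1 SYNTF1
A  [  1  1  1 97  1 97 97  1  1  1  1 97 ]
C  [  1  1 97  1  1  1  1 97  1  1 97  1 ]
G  [  1 97  1  1  1  1  1  1 97  1  1  1 ]
T  [ 97  1  1  1 97  1  1  1  1 97  1  1 ]
>SYN0002.1 SYNTF2
A  [ 90  2  2  2 90  2  2 90  2  2 ]
C  [  4 90  2  2  4  2 90  4  2 90 ]
G  [  4  4 90  2  4  2  4  4 90  4 ]
T  [  2  4  6 94  2 94  4  2  6  4 ]
>SYN0003.1 SYNTF3
A  [  2  2 85  5  2  5  2 85  2  2  5 ]
C  [ 85  5  5  2  2  2 85  5  2  2  2 ]
G  [  8 85  5  5  2  2  8  5 85  2  2 ]
T  [  5  8  5 88 94 91  5  5 11 94 91 ]
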