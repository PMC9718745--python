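>SYN0001 SP1
A [   1   1   1   1   1   1   1   1   1   1 ]
C [   1   1   1   1  97   1   1   1   1  97 ]
G [  97  97  97  97   1  97  97  97  97   1 ]
T [   1   1   1   1   1   1   1   1   1   1 ]
>SYN0002 EGR-1
A [   1   1   1   1   1   1   1   1   1 ]
C [   1  97   1   1   1   1   1  97   1 ]
G [  97   1  97   1  97  97  97   1  97 ]
T [   1   1   1  97   1   1   1   1   1 ]
>SYN0003 ER
A [   1   1   1   1  97   1  97   1   1   1  97   1   1 ]
C [   1   1   1  97   1  97   1   1   1   1   1  97  97 ]
G [  97  97   1   1   1   1   1  97   1  97   1   1   1 ]
T [   1   1  97   1   1   1   1   1  97   1   1   1   1 ]
>SYN0004 GATA-1
A [  97   1  97   1  97  97   1  97 ]
C [   1   1   1   1   1   1   1   1 ]
G [   1  97   1   1   1   1  97   1 ]
T [   1   1   1  97   1   1   1   1 ]
>SYN0005 GR
A [  97   1  97  97   1  97   1   1   1   1   1   1   1   1   1 ]
C [   1   1   1   1  97   1   1   1  97   1   1   1   1  97   1 ]
G [   1  97   1   1   1   1   1   1   1   1  97   1   1   1   1 ]
T [   1   1   1   1   1   1  97  97   1  97   1  97  97   1  97 ]
>SYN0006 c-JUN
A [   1   1  97   1   1   1  97 ]
C [   1   1   1  97   1  97   1 ]
G [   1  97   1   1   1   1   1 ]
T [  97   1   1   1  97   1   1 ]
>SYN0007 YY1
A [   1   1   1   1  97   1   1   1   1 ]
C [  97   1  97  97   1   1   1   1   1 ]
G [   1  97   1   1   1   1   1   1   1 ]
T [   1   1   1   1   1  97  97  97  97 ]
>SYN0008 ATF
A [   1   1  97   1   1   1   1  97 ]
C [   1   1   1  97   1   1  97   1 ]
G [   1  97   1   1  97   1   1   1 ]
T [  97   1   1   1   1  97   1   1 ]
>SYN0009 CREB
A [   1   1  97   1   1   1   1  97   1 ]
C [   1   1   1  97   1   1  97   1   1 ]
G [   1  97   1   1  97   1   1   1  97 ]
T [  97   1   1   1   1  97   1   1   1 ]
>SYN0010 ELK1
A [  97   1   1   1   1  97  97   1   1 ]
C [   1  97  97   1   1   1   1   1   1 ]
G [   1   1   1  97  97   1   1  97   1 ]
T [   1   1   1   1   1   1   1   1  97 ]
>SYN0011 c-FOS
A [  97   1   1  97   1   1   1  97   1 ]
C [   1   1   1   1  97   1  97   1   1 ]
G [   1   1  97   1   1   1   1   1   1 ]
T [   1  97   1   1   1  97   1   1  97 ]
>SYN0012 MYC
A [   1   1  97   1   1   1   1   1 ]
C [  97  97   1  97   1   1   1   1 ]
G [   1   1   1   1  97   1  97  97 ]
T [   1   1   1   1   1  97   1   1 ]
>SYN0013 E2F
A [   1   1   1   1   1   1   1   1 ]
C [   1   1   1  97   1  97   1  97 ]
G [   1   1   1   1  97   1  97   1 ]
T [  97  97  97   1   1   1   1   1 ]
>SYN0014 HOXA5
A [   1   1  97  97   1   1  97   1 ]
C [  97   1   1   1   1   1   1   1 ]
G [   1   1   1   1   1   1   1  97 ]
T [   1  97   1   1  97  97   1   1 ]
>SYN0015 HNF4
A [   1   1   1   1   1  97  97  97   1   1   1   1  97 ]
C [   1   1   1   1  97   1   1   1   1   1   1  97   1 ]
G [  97  97  97   1   1   1   1   1  97  97   1   1   1 ]
T [   1   1   1  97   1   1   1   1   1   1  97   1   1 ]
>SYN0016 MEF2
A [   1   1  97   1   1   1   1   1  97   1 ]
C [  97   1   1   1   1   1   1   1   1   1 ]
G [   1   1   1   1   1   1   1   1   1  97 ]
T [   1  97   1  97  97  97  97  97   1   1 ]
>SYN0017 PPAR
A [   1   1  97   1   1   1   1   1   1  97   1   1   1 ]
C [   1   1   1  97  97   1   1   1   1   1  97  97   1 ]
G [   1  97   1   1   1   1   1   1  97   1   1   1   1 ]
T [  97   1   1   1   1  97  97  97   1   1   1   1  97 ]
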