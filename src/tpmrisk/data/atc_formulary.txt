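A01AA
A01BA
A01CA
A01DA
A01EA
A01FA
A02AA
A02BA
A02BC
A02CA
A02DA
A02EA
A02FA
A03AA
A03BA
A03CA
A03DA
A03EA
A03FA
A04AA
A04BA
A04CA
A04DA
A04EA
A04FA
A05AA
A05BA
A05CA
A05DA
A05EA
A05FA
A06AA
A06BA
A06CA
A06DA
A06EA
A06FA
A07AA
A07BA
A07CA
A07DA
A07EA
A07EC
A07EX01
A07FA
A08AA
A08BA
A08CA
A08DA
A08EA
A08FA
A09AA
A09BA
A09CA
A09DA
A09EA
A09FA
A10AA
A10BA
A10CA
A10DA
A10EA
A10FA
A11AA
A11BA
A11CA
A11CC
A11DA
A11EA
A11FA
A12AA
A12BA
A12CA
A12DA
A12EA
A12FA
B01AA
B01AC
B01BA
B01CA
B01DA
B01EA
B01FA
B02AA
B02BA
B02CA
B02DA
B02EA
B02FA
B03AA
B03BA
B03CA
B03DA
B03EA
B03FA
B04AA
B04BA
B04CA
B04DA
B04EA
B04FA
B05AA
B05BA
B05CA
B05DA
B05EA
B05FA
B06AA
B06BA
B06CA
B06DA
B06EA
B06FA
B07AA
B07BA
B07CA
B07DA
B07EA
B07FA
B08AA
B08BA
B08CA
B08DA
B08EA
B08FA
B09AA
B09BA
B09CA
B09DA
B09EA
B09FA
B10AA
B10BA
B10CA
B10DA
B10EA
B10FA
B11AA
B11BA
B11CA
B11DA
B11EA
B11FA
B12AA
B12BA
B12CA
B12DA
B12EA
B12FA
C01AA
C01BA
C01CA
C01DA
C01EA
C01FA
C02AA
C02BA
C02CA
C02DA
C02EA
C02FA
C03AA
C03BA
C03CA
C03DA
C03EA
C03FA
C04AA
C04BA
C04CA
C04DA
C04EA
C04FA
C05AA
C05BA
C05CA
C05DA
C05EA
C05FA
C06AA
C06BA
C06CA
C06DA
C06EA
C06FA
C07AA
C07AB
C07BA
C07CA
C07DA
C07EA
C07FA
C08AA
C08BA
C08CA
C08DA
C08EA
C08FA
C09AA
C09BA
C09CA
C09DA
C09EA
C09FA
C10AA
C10BA
C10CA
C10DA
C10EA
C10FA
C11AA
C11BA
C11CA
C11DA
C11EA
C11FA
C12AA
C12BA
C12CA
C12DA
C12EA
C12FA
D01AA
D01BA
D01CA
D01DA
D01EA
D01FA
D02AA
D02BA
D02CA
D02DA
D02EA
D02FA
D03AA
D03BA
D03CA
D03DA
D03EA
D03FA
D04AA
D04BA
D04CA
D04DA
D04EA
D04FA
D05AA
D05AX02
D05AX03
D05BA
D05BB
D05CA
D05DA
D05EA
D05FA
D06AA
D06BA
D06CA
D06DA
D06EA
D06FA
D07AA
D07AC
D07BA
D07CA
D07DA
D07EA
D07FA
D08AA
D08BA
D08CA
D08DA
D08EA
D08FA
D09AA
D09BA
D09CA
D09DA
D09EA
D09FA
D10AA
D10BA
D10CA
D10DA
D10EA
D10FA
D11AA
D11BA
D11CA
D11DA
D11EA
D11FA
D12AA
D12BA
D12CA
D12DA
D12EA
D12FA
G01AA
G01BA
G01CA
G01DA
G01EA
G01FA
G02AA
G02BA
G02CA
G02DA
G02EA
G02FA
G03AA
G03AX01
G03BA
G03CA
G03DA
G03EA
G03FA
G04AA
G04BA
G04CA
G04DA
G04EA
G04FA
G05AA
G05BA
G05CA
G05DA
G05EA
G05FA
G06AA
G06BA
G06CA
G06DA
G06EA
G06FA
G07AA
G07BA
G07CA
G07DA
G07EA
G07FA
G08AA
G08BA
G08CA
G08DA
G08EA
G08FA
G09AA
G09BA
G09CA
G09DA
G09EA
G09FA
G10AA
G10BA
G10CA
G10DA
G10EA
G10FA
G11AA
G11BA
G11CA
G11DA
G11EA
G11FA
G12AA
G12BA
G12CA
G12DA
G12EA
G12FA
H01AA
H01BA
H01CA
H01DA
H01EA
H01FA
H02AA
H02AB
H02BA
H02CA
H02DA
H02EA
H02FA
H03AA
H03BA
H03CA
H03DA
H03EA
H03FA
H04AA
H04BA
H04CA
H04DA
H04EA
H04FA
H05AA
H05BA
H05CA
H05DA
H05EA
H05FA
H06AA
H06BA
H06CA
H06DA
H06EA
H06FA
H07AA
H07BA
H07CA
H07DA
H07EA
H07FA
H08AA
H08BA
H08CA
H08DA
H08EA
H08FA
H09AA
H09BA
H09CA
H09DA
H09EA
H09FA
H10AA
H10BA
H10CA
H10DA
H10EA
H10FA
H11AA
H11BA
H11CA
H11DA
H11EA
H11FA
H12AA
H12BA
H12CA
H12DA
H12EA
H12FA
J01AA
J01BA
J01CA
J01DA
J01EA
J01FA
J02AA
J02BA
J02CA
J02DA
J02EA
J02FA
J03AA
J03BA
J03CA
J03DA
J03EA
J03FA
J04AA
J04BA
J04CA
J04DA
J04EA
J04FA
J05AA
J05BA
J05CA
J05DA
J05EA
J05FA
J06AA
J06BA
J06CA
J06DA
J06EA
J06FA
J07AA
J07BA
J07CA
J07DA
J07EA
J07FA
J08AA
J08BA
J08CA
J08DA
J08EA
J08FA
J09AA
J09BA
J09CA
J09DA
J09EA
J09FA
J10AA
J10BA
J10CA
J10DA
J10EA
J10FA
J11AA
J11BA
J11CA
J11DA
J11EA
J11FA
J12AA
J12BA
J12CA
J12DA
J12EA
J12FA
L01AA
L01BA
L01CA
L01DA
L01EA
L01FA
L02AA
L02BA
L02CA
L02DA
L02EA
L02FA
L03AA
L03BA
L03CA
L03DA
L03EA
L03FA
L04AA
L04AD
L04AX01
L04AX03
L04BA
L04CA
L04DA
L04EA
L04FA
L05AA
L05BA
L05CA
L05DA
L05EA
L05FA
L06AA
L06BA
L06CA
L06DA
L06EA
L06FA
L07AA
L07BA
L07CA
L07DA
L07EA
L07FA
L08AA
L08BA
L08CA
L08DA
L08EA
L08FA
L09AA
L09BA
L09CA
L09DA
L09EA
L09FA
L10AA
L10BA
L10CA
L10DA
L10EA
L10FA
L11AA
L11BA
L11CA
L11DA
L11EA
L11FA
L12AA
L12BA
L12CA
L12DA
L12EA
L12FA
M01AA
M01AB
M01AE
M01BA
M01CA
M01DA
M01EA
M01FA
M02AA
M02BA
M02CA
M02DA
M02EA
M02FA
M03AA
M03BA
M03CA
M03DA
M03EA
M03FA
M04AA
M04BA
M04CA
M04DA
M04EA
M04FA
M05AA
M05BA
M05BX03
M05CA
M05DA
M05EA
M05FA
M06AA
M06BA
M06CA
M06DA
M06EA
M06FA
M07AA
M07BA
M07CA
M07DA
M07EA
M07FA
M08AA
M08BA
M08CA
M08DA
M08EA
M08FA
M09AA
M09BA
M09CA
M09DA
M09EA
M09FA
M10AA
M10BA
M10CA
M10DA
M10EA
M10FA
M11AA
M11BA
M11CA
M11DA
M11EA
M11FA
M12AA
M12BA
M12CA
M12DA
M12EA
M12FA
N01AA
N01BA
N01CA
N01DA
N01EA
N01FA
N02AA
N02BA
N02BE
N02CA
N02DA
N02EA
N02FA
N03AA
N03BA
N03CA
N03DA
N03EA
N03FA
N04AA
N04BA
N04CA
N04DA
N04EA
N04FA
N05AA
N05BA
N05CA
N05DA
N05EA
N05FA
N06AA
N06AB
N06AX11
N06BA
N06CA
N06DA
N06EA
N06FA
N07AA
N07BA
N07CA
N07DA
N07EA
N07FA
N08AA
N08BA
N08CA
N08DA
N08EA
N08FA
N09AA
N09BA
N09CA
N09DA
N09EA
N09FA
N10AA
N10BA
N10CA
N10DA
N10EA
N10FA
N11AA
N11BA
N11CA
N11DA
N11EA
N11FA
N12AA
N12BA
N12CA
N12DA
N12EA
N12FA
P01AA
P01BA
P01CA
P01DA
P01EA
P01FA
P02AA
P02BA
P02CA
P02DA
P02EA
P02FA
P03AA
P03BA
P03CA
P03DA
P03EA
P03FA
P04AA
P04BA
P04CA
P04DA
P04EA
P04FA
P05AA
P05BA
P05CA
P05DA
P05EA
P05FA
P06AA
P06BA
P06CA
P06DA
P06EA
P06FA
P07AA
P07BA
P07CA
P07DA
P07EA
P07FA
P08AA
P08BA
P08CA
P08DA
P08EA
P08FA
P09AA
P09BA
P09CA
P09DA
P09EA
P09FA
P10AA
P10BA
P10CA
P10DA
P10EA
P10FA
P11AA
P11BA
P11CA
P11DA
P11EA
P11FA
P12AA
P12BA
P12CA
P12DA
P12EA
P12FA
R01AA
R01BA
R01CA
R01DA
R01EA
R01FA
R02AA
R02BA
R02CA
R02DA
R02EA
R02FA
R03AC
R03DX05
R06AE
S01AA
V03AX02
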