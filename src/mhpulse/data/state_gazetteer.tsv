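# US state gazetteer: alias<TAB>canonical state name.
# Full names match case-insensitively at word boundaries; two-letter USPS
# abbreviations match only as exact upper-case standalone tokens.
Alabama	Alabama
AL	Alabama
Alaska	Alaska
AK	Alaska
Arizona	Arizona
AZ	Arizona
Arkansas	Arkansas
AR	Arkansas
California	California
CA	California
Colorado	Colorado
CO	Colorado
Connecticut	Connecticut
CT	Connecticut
Delaware	Delaware
DE	Delaware
Florida	Florida
FL	Florida
Georgia	Georgia
GA	Georgia
Hawaii	Hawaii
HI	Hawaii
Idaho	Idaho
ID	Idaho
Illinois	Illinois
IL	Illinois
Indiana	Indiana
IN	Indiana
Iowa	Iowa
IA	Iowa
Kansas	Kansas
KS	Kansas
Kentucky	Kentucky
KY	Kentucky
Louisiana	Louisiana
LA	Louisiana
Maine	Maine
ME	Maine
Maryland	Maryland
MD	Maryland
Massachusetts	Massachusetts
MA	Massachusetts
Michigan	Michigan
MI	Michigan
Minnesota	Minnesota
MN	Minnesota
Mississippi	Mississippi
MS	Mississippi
Missouri	Missouri
MO	Missouri
Montana	Montana
MT	Montana
Nebraska	Nebraska
NE	Nebraska
Nevada	Nevada
NV	Nevada
New Hampshire	New Hampshire
NH	New Hampshire
New Jersey	New Jersey
NJ	New Jersey
New Mexico	New Mexico
NM	New Mexico
New York	New York
NY	New York
North Carolina	North Carolina
NC	North Carolina
North Dakota	North Dakota
ND	North Dakota
Ohio	Ohio
OH	Ohio
Oklahoma	Oklahoma
OK	Oklahoma
Oregon	Oregon
OR	Oregon
Pennsylvania	Pennsylvania
PA	Pennsylvania
Rhode Island	Rhode Island
RI	Rhode Island
South Carolina	South Carolina
SC	South Carolina
South Dakota	South Dakota
SD	South Dakota
Tennessee	Tennessee
TN	Tennessee
Texas	Texas
TX	Texas
Utah	Utah
UT	Utah
Vermont	Vermont
VT	Vermont
Virginia	Virginia
VA	Virginia
Washington	Washington
WA	Washington
West Virginia	West Virginia
WV	West Virginia
Wisconsin	Wisconsin
WI	Wisconsin
Wyoming	Wyoming
WY	Wyoming
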