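%
1	anxiety
2	anger
3	sad
4	posemo
5	social
6	prosocial
%
angst*	1
panik*	1
furcht*	1
sorge*	1
sorgen*	1
risik*	1
unsicher*	1
nervös*	1
bange	1
beunruhig*	1
bedroh*	1
gefahr*	1
gefährlich*	1
erschreck*	1
schock*	1
alarm*	1
zweifel*	1
stress*	1
zitter*	1
terror*	1	2
wut*	2
wüten*	2
zorn*	2
hass*	2
ärger*	2
toete*	2
töt*	2
töte*	2
aggress*	2
streit*	2
kampf*	2
gewalt*	2
beschimpf*	2
empör*	2
feind*	2
brutal*	2
attack*	2
krieg*	2
rache*	2
mord*	2
traurig*	3
trauer*	3
tot*	3
wein*	3
klagen*	3
harm*	3
miss*	3
verlust*	3
leid*	3
schmerz*	3
verzweif*	3
einsam*	3
vermiss*	3
depress*	3
elend*	3
kummer*	3
verabschied*	3
trän*	3
sterb*	3
grab*	3
liebe*	4
freude*	4
froh*	4
glück*	4
schön*	4
lach*	4
spass	4
spaß	4
hoffnung*	4
optimis*	4
wunderbar*	4
toll*	4
super	4
mutig*	4
dank*	4
stolz*	4
aww*	4
hugs	4
bewunder*	4
heilte	4
geheilt	4
heilt	4
heilte*	4
heilung	4
äußerst	4
freund*	5
familie*	5
gemeinsam*	5
zusammen*	5
reden*	5
sprech*	5
gespräch*	5
teilnehm*	5
besuch*	5
nachbar*	5
kolleg*	5
empfehlung*	5
moin	5
gn	5
gruß*	5
grüß*	5
wir	5
uns	5
ihr	5
euch	5
helf*	6
hilfe*	6
hilfsbereit*	6
dienst*	6
spende*	6
freiwillig*	6
unterstütz*	6
empath*	6
mitgefühl*	6
kooperier*	6
zusammenarbeit*	6
teilen	6
teilt mit	6
solidar*	6
fürsorg*	6
pfleg*	6
trost*	6
ermutig*	6
gemeinschaft*	6
behandlung	6
behandlungen	6
heilverfahren	6
öffentlicher dienst	6
digitale dienste	6
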