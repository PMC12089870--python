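# Surname gazetteer (public-domain common family names).
# Curated to avoid ordinary English words, place names, and medication lookalikes.
adams
aguilar
alvarez
anderson
andrews
armstrong
bailey
barnes
becker
bennett
benson
berger
blackwell
boyd
bradley
brennan
brooks
bryant
burke
butler
caldwell
campbell
carlson
carpenter
carter
castillo
chambers
chavez
clark
coleman
collins
conner
cooper
cortez
cruz
cunningham
curtis
daniels
davidson
davis
dawson
delgado
diaz
dixon
dominguez
donovan
douglas
doyle
duncan
dunn
edwards
elliott
ellis
erickson
espinoza
evans
farrell
ferguson
fernandez
figueroa
fisher
fitzgerald
fleming
flores
foster
fowler
franklin
fraser
freeman
fuentes
gallagher
garcia
gardner
garrett
gibson
gilbert
gomez
gonzalez
goodwin
graham
grant
greene
griffin
gutierrez
hamilton
hansen
hanson
harper
harrington
harris
harrison
hayes
henderson
hendricks
hernandez
herrera
higgins
hoffman
holloway
holmes
hopkins
horton
howell
hudson
hughes
hutchinson
ibarra
ingram
jackson
jacobs
jenkins
jensen
jimenez
johnson
johnston
jones
jordan
juarez
kaufman
keller
kennedy
kerr
kim
kirby
klein
kramer
lambert
larson
lawrence
lawson
lee
leonard
lewis
lindsey
lopez
lowe
lucas
lynch
macdonald
maldonado
malone
manning
marquez
marshall
martinez
mason
matthews
maxwell
mcbride
mccarthy
mccormick
mcdonald
mcgee
mckenzie
mclaughlin
medina
mendez
mendoza
meyer
miller
mitchell
molina
montgomery
moran
moreno
morgan
morrison
morton
mueller
mullins
munoz
murphy
murray
myers
navarro
nelson
newman
nguyen
nichols
nielsen
nolan
norton
nunez
obrien
ochoa
oconnor
odonnell
oliver
olsen
olson
ortega
ortiz
osborne
owens
pacheco
padilla
palmer
park
parker
parsons
patel
patterson
paulson
pearson
pena
perez
perkins
peterson
phillips
pierce
porter
powell
powers
pratt
preston
quinn
ramirez
ramos
randall
reed
reeves
reilly
reyes
reynolds
richards
richardson
riley
rivera
roberts
robertson
robinson
rodgers
rodriguez
rogers
rojas
romero
rosales
ross
rowe
russell
ryan
salazar
salinas
sanchez
sanders
sandoval
santiago
santos
sawyer
schmidt
schneider
schroeder
schultz
schwartz
scott
sellers
serrano
sharp
shaw
shepherd
sherman
simmons
simpson
sims
singh
skinner
sloan
smith
snyder
solis
soto
spencer
stafford
stanton
steele
stephens
stevens
stevenson
stewart
stokes
sullivan
sutton
swanson
sweeney
tanner
taylor
thompson
thornton
torres
townsend
tran
travis
tucker
turner
underwood
valdez
valencia
vance
vargas
vasquez
vaughn
vazquez
vega
velasquez
wagner
walker
wallace
walsh
walton
ward
warren
watkins
watson
weaver
webb
weber
welch
wheeler
whitaker
wilkins
wilkinson
williams
williamson
willis
wilson
winters
wolfe
woods
wright
yates
zamora
zimmerman
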